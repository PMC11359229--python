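city_id,delta_ml,delta_d2d
Beijing,-26,-3.7
Tianjin,-18,-13
Shijiazhuang,-18,-9.6
Taiyuan,-11,-5.5
Hohhot,-11,-18
Shenyang,-17,-15
Changchun,-19,-18
Harbin,-19,-21
Shanghai,-18,-15
Nanjing,-18,-14
Hangzhou,-21,-16
Hefei,-14,-15
Fuzhou,-12,-10
Nanchang,-17,-19
Jinan,-21,-13
Zhengzhou,-18,-10
Wuhan,-29,-25
Changsha,-19,-13
Guangzhou,-23,-20
Nanning,-14,-6.4
Haikou,-5,-4.4
Chongqing,-15,-13
Chengdu,-20,-12
Guiyang,-9,-5.4
Kunming,-14,-13
Lhasa,-6.9,-0.63
Xi'an,-21,-12
Lanzhou,-8.2,-3.7
Xining,-5.8,-1.5
Yinchuan,-12,-8.2
Urumqi,-20,-21
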