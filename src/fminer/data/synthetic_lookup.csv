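raw,standard
Huangqi,Huangqi
Dangshen,Dangshen
Baizhu,Baizhu
Fuling,Fuling
Gancao,Gancao
Danggui,Danggui
Chuanxiong,Chuanxiong
Baishao,Baishao
Shudihuang,Shudihuang
Renshen,Renshen
Guizhi,Guizhi
Shengjiang,Shengjiang
Dazao,Dazao
Mahuang,Mahuang
Xingren,Xingren
Shigao,Shigao
Zhimu,Zhimu
Huanglian,Huanglian
Huangqin,Huangqin
Huangbai,Huangbai
Zhizi,Zhizi
Chaihu,Chaihu
Banxia,Banxia
Chenpi,Chenpi
Houpo,Houpo
Zhishi,Zhishi
Dahuang,Dahuang
Mangxiao,Mangxiao
Taoren,Taoren
Honghua,Honghua
Chishao,Chishao
Shengdihuang,Shengdihuang
Maidong,Maidong
Wuweizi,Wuweizi
Suanzaoren,Suanzaoren
Yuanzhi,Yuanzhi
Shichangpu,Shichangpu
Longgu,Longgu
Muli,Muli
Gegen,Gegen
Jiegeng,Jiegeng
Bohe,Bohe
Jingjie,Jingjie
Fangfeng,Fangfeng
Qianghuo,Qianghuo
Duhuo,Duhuo
Niubangzi,Niubangzi
Lianqiao,Lianqiao
Jinyinhua,Jinyinhua
Pugongying,Pugongying
Yiyiren,Yiyiren
Zexie,Zexie
Zhuling,Zhuling
Cangzhu,Cangzhu
Sharen,Sharen
Muxiang,Muxiang
Xiangfu,Xiangfu
Yanhusuo,Yanhusuo
Danshen,Danshen
Sanqi,Sanqi
Huang Qi,Huangqi
Dang Shen,Dangshen
Bai Zhu,Baizhu
Fu Ling,Fuling
Gan Cao,Gancao
Dang Gui,Danggui
Chuan Xiong,Chuanxiong
Bai Shao,Baishao
Shu Di Huang,Shudihuang
Ren Shen,Renshen
Gui Zhi,Guizhi
Sheng Jiang,Shengjiang
Da Zao,Dazao
Ma Huang,Mahuang
Xing Ren,Xingren
Shi Gao,Shigao
Zhi Mu,Zhimu
Huang Lian,Huanglian
Huang Qin,Huangqin
Huang Bai,Huangbai
Zhi Zi,Zhizi
Chai Hu,Chaihu
Ban Xia,Banxia
Chen Pi,Chenpi
Hou Po,Houpo
Zhi Shi,Zhishi
Da Huang,Dahuang
Mang Xiao,Mangxiao
Tao Ren,Taoren
Hong Hua,Honghua
Chi Shao,Chishao
Sheng Di Huang,Shengdihuang
Mai Dong,Maidong
Wu Wei Zi,Wuweizi
Suan Zao Ren,Suanzaoren
Yuan Zhi,Yuanzhi
Shi Chang Pu,Shichangpu
Long Gu,Longgu
Mu Li,Muli
Ge Gen,Gegen
Jie Geng,Jiegeng
Bo He,Bohe
Jing Jie,Jingjie
Fang Feng,Fangfeng
Qiang Huo,Qianghuo
Du Huo,Duhuo
Niu Bang Zi,Niubangzi
Lian Qiao,Lianqiao
Jin Yin Hua,Jinyinhua
Pu Gong Ying,Pugongying
Yi Yi Ren,Yiyiren
Ze Xie,Zexie
Zhu Ling,Zhuling
Cang Zhu,Cangzhu
Sha Ren,Sharen
Mu Xiang,Muxiang
Xiang Fu,Xiangfu
Yan Hu Suo,Yanhusuo
Dan Shen,Danshen
San Qi,Sanqi
黄芪,Huangqi
白术,Baizhu
茯苓,Fuling
甘草,Gancao
当归,Danggui
白芍,Baishao
熟地黄,Shudihuang
人参,Renshen
桂枝,Guizhi
麻黄,Mahuang
黄连,Huanglian
黄芩,Huangqin
黄柏,Huangbai
柴胡,Chaihu
半夏,Banxia
陈皮,Chenpi
大黄,Dahuang
生地黄,Shengdihuang
连翘,Lianqiao
金银花,Jinyinhua
丹参,Danshen
三七,Sanqi
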