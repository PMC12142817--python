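formula_id,ingredient
Guizhi Tang,Guizhi
Guizhi Tang,Baishao
Guizhi Tang,Shengjiang
Guizhi Tang,Dazao
Guizhi Tang,Gancao
Mahuang Tang,Mahuang
Mahuang Tang,Guizhi
Mahuang Tang,Xingren
Mahuang Tang,Gancao
Baihu Tang,Shigao
Baihu Tang,Zhimu
Baihu Tang,Gancao
Sijunzi Tang,Renshen
Sijunzi Tang,Baizhu
Sijunzi Tang,Fuling
Sijunzi Tang,Gancao
Siwu Tang,Danggui
Siwu Tang,Chuanxiong
Siwu Tang,Baishao
Siwu Tang,Shudihuang
Buzhong Yiqi Tang,Huangqi
Buzhong Yiqi Tang,Renshen
Buzhong Yiqi Tang,Baizhu
Buzhong Yiqi Tang,Gancao
Buzhong Yiqi Tang,Danggui
Buzhong Yiqi Tang,Chenpi
Buzhong Yiqi Tang,Chaihu
Xiaochaihu Tang,Chaihu
Xiaochaihu Tang,Huangqin
Xiaochaihu Tang,Banxia
Xiaochaihu Tang,Renshen
Xiaochaihu Tang,Gancao
Xiaochaihu Tang,Shengjiang
Xiaochaihu Tang,Dazao
Erchen Tang,Banxia
Erchen Tang,Chenpi
Erchen Tang,Fuling
Erchen Tang,Gancao
Huanglian Jiedu Tang,Huanglian
Huanglian Jiedu Tang,Huangqin
Huanglian Jiedu Tang,Huangbai
Huanglian Jiedu Tang,Zhizi
Taohong Siwu Tang,Taoren
Taohong Siwu Tang,Honghua
Taohong Siwu Tang,Danggui
Taohong Siwu Tang,Chuanxiong
Taohong Siwu Tang,Baishao
Taohong Siwu Tang,Shudihuang
Suanzaoren Tang,Suanzaoren
Suanzaoren Tang,Zhimu
Suanzaoren Tang,Fuling
Suanzaoren Tang,Chuanxiong
Suanzaoren Tang,Gancao
Yinqiao San,Jinyinhua
Yinqiao San,Lianqiao
Yinqiao San,Jiegeng
Yinqiao San,Bohe
Yinqiao San,Niubangzi
Yinqiao San,Jingjie
Yinqiao San,Gancao
Pingwei San,Cangzhu
Pingwei San,Houpo
Pingwei San,Chenpi
Pingwei San,Gancao
Wuling San,Zexie
Wuling San,Zhuling
Wuling San,Fuling
Wuling San,Baizhu
Wuling San,Guizhi
Dachengqi Tang,Dahuang
Dachengqi Tang,Mangxiao
Dachengqi Tang,Zhishi
Dachengqi Tang,Houpo
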