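herb,nature,flavors,meridians,efficacy_class
Huangqi,warm,sweet,Lung|Spleen,tonifying/qi
Dangshen,neutral,sweet,Lung|Spleen,tonifying/qi
Baizhu,warm,sweet|bitter,Spleen|Stomach,tonifying/qi
Fuling,neutral,sweet|bland,Heart|Spleen|Kidney,draining-dampness/water
Gancao,neutral,sweet,Heart|Lung|Spleen|Stomach,tonifying/qi
Danggui,warm,sweet|pungent,Liver|Heart|Spleen,tonifying/blood
Chuanxiong,warm,pungent,Liver|Gallbladder|Pericardium,regulating-blood/invigorating
Baishao,cool,bitter|sour,Liver|Spleen,tonifying/blood
Shudihuang,warm,sweet,Liver|Kidney,tonifying/blood
Renshen,warm,sweet|bitter,Lung|Spleen|Heart,tonifying/qi
Guizhi,warm,pungent|sweet,Heart|Lung|Bladder,releasing-exterior/warm
Shengjiang,warm,pungent,Lung|Spleen|Stomach,releasing-exterior/warm
Dazao,warm,sweet,Spleen|Stomach,tonifying/qi
Mahuang,warm,pungent|bitter,Lung|Bladder,releasing-exterior/warm
Xingren,warm,bitter,Lung|Large Intestine,relieving-cough/descending
Shigao,cold,pungent|sweet,Lung|Stomach,clearing-heat/fire
Zhimu,cold,bitter|sweet,Lung|Stomach|Kidney,clearing-heat/fire
Huanglian,cold,bitter,Heart|Spleen|Stomach|Liver|Gallbladder|Large Intestine,clearing-heat/dampness
Huangqin,cold,bitter,Lung|Gallbladder|Spleen|Large Intestine|Small Intestine,clearing-heat/dampness
Huangbai,cold,bitter,Kidney|Bladder,clearing-heat/dampness
Zhizi,cold,bitter,Heart|Lung|Triple Burner,clearing-heat/fire
Chaihu,cool,bitter|pungent,Liver|Gallbladder,releasing-exterior/cool
Banxia,warm,pungent,Spleen|Stomach|Lung,resolving-phlegm/warm
Chenpi,warm,pungent|bitter,Spleen|Lung,regulating-qi/moving
Houpo,warm,bitter|pungent,Spleen|Stomach|Lung|Large Intestine,regulating-qi/moving
Zhishi,cool,bitter|pungent,Spleen|Stomach|Large Intestine,regulating-qi/moving
Dahuang,cold,bitter,Spleen|Stomach|Large Intestine|Liver|Pericardium,purgative/attacking
Mangxiao,cold,salty|bitter,Stomach|Large Intestine,purgative/attacking
Taoren,neutral,bitter|sweet,Heart|Liver|Large Intestine,regulating-blood/invigorating
Honghua,warm,pungent,Heart|Liver,regulating-blood/invigorating
Chishao,cool,bitter,Liver,clearing-heat/blood
Shengdihuang,cold,sweet|bitter,Heart|Liver|Kidney,clearing-heat/blood
Maidong,cool,sweet|bitter,Heart|Lung|Stomach,tonifying/yin
Wuweizi,warm,sour|sweet,Lung|Heart|Kidney,astringent/securing
Suanzaoren,neutral,sweet|sour,Liver|Gallbladder|Heart,calming-spirit/nourishing
Yuanzhi,warm,bitter|pungent,Heart|Kidney|Lung,calming-spirit/nourishing
Shichangpu,warm,pungent|bitter,Heart|Stomach,opening-orifices/aromatic
Longgu,neutral,sweet|astringent,Heart|Liver|Kidney,calming-spirit/settling
Muli,cool,salty|astringent,Liver|Gallbladder|Kidney,calming-spirit/settling
Gegen,cool,sweet|pungent,Spleen|Stomach,releasing-exterior/cool
Jiegeng,neutral,bitter|pungent,Lung,resolving-phlegm/cold
Bohe,cool,pungent,Lung|Liver,releasing-exterior/cool
Jingjie,warm,pungent,Lung|Liver,releasing-exterior/warm
Fangfeng,warm,pungent|sweet,Bladder|Liver|Spleen,releasing-exterior/warm
Qianghuo,warm,pungent|bitter,Bladder|Kidney,releasing-exterior/warm
Duhuo,warm,pungent|bitter,Kidney|Bladder,dispelling-wind-damp/cold
Niubangzi,cold,pungent|bitter,Lung|Stomach,releasing-exterior/cool
Lianqiao,cool,bitter,Lung|Heart|Small Intestine,clearing-heat/toxin
Jinyinhua,cold,sweet,Lung|Heart|Stomach,clearing-heat/toxin
Pugongying,cold,bitter|sweet,Liver|Stomach,clearing-heat/toxin
Yiyiren,cool,sweet|bland,Spleen|Stomach|Lung,draining-dampness/water
Zexie,cold,sweet|bland,Kidney|Bladder,draining-dampness/water
Zhuling,neutral,sweet|bland,Kidney|Bladder,draining-dampness/water
Cangzhu,warm,pungent|bitter,Spleen|Stomach,transforming-dampness/aromatic
Sharen,warm,pungent,Spleen|Stomach|Kidney,transforming-dampness/aromatic
Muxiang,warm,pungent|bitter,Spleen|Stomach|Large Intestine|Triple Burner|Gallbladder,regulating-qi/moving
Xiangfu,neutral,pungent|bitter|sweet,Liver|Spleen|Triple Burner,regulating-qi/moving
Yanhusuo,warm,pungent|bitter,Liver|Spleen,regulating-blood/invigorating
Danshen,cool,bitter,Heart|Pericardium|Liver,regulating-blood/invigorating
Sanqi,warm,sweet|bitter,Liver|Stomach,regulating-blood/stanching
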