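site_id,season,k,label_printed
Lipnik,2018/19,1.2,relatively_dry
Lipnik,2019/20,2.7,humid
Mochełek,2018/19,0.7,dry
Mochełek,2019/20,3.0,humid
Winna Góra,2018/19,1.0,dry
Winna Góra,2019/20,0.8,dry
Czesławice,2018/19,1.5,optimal
Czesławice,2019/20,4.0,humid
Swojczyce,2018/19,1.5,optimal
Swojczyce,2019/20,2.4,humid
Wrocław,2018/19,1.1,relatively_dry
Wrocław,2019/20,1.6,optimal
Mydlniki,2018/19,3.3,humid
Mydlniki,2019/20,2.0,humid
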