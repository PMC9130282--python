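site_id,season,sowing_date,harvest_date,wheat_emergence_date,blackgrass_emergence_date,printed_days_to_wheat,printed_blackgrass_delay
Lipnik,2018/19,18.10.2018,10.07.2019,25.10.2018,25.10.2018,8,0
Mochełek,2018/19,17.10.2018,03.07.2019,02.11.2018,02.11.2018,16,0
Winna Góra,2018/19,18.10.2018,11.07.2019,30.10.2018,05.11.2018,12,6
Czesławice,2018/19,09.10.2018,24.07.2019,23.10.2018,25.10.2018,15,2
Swojczyce,2018/19,13.10.2018,17.07.2019,23.10.2018,26.10.2018,10,3
Wrocław,2018/19,25.10.2018,18.07.2019,05.11.2018,08.11.2018,11,3
Mydlniki,2018/19,04.10.2018,13.06.2019,12.10.2018,18.10.2018,8,6
Lipnik,2019/20,17.10.2019,19.07.2020,25.10.2019,29.10.2019,9,4
Mochełek,2019/20,17.10.2019,08.07.2020,02.11.2019,02.11.2019,16,0
Winna Góra,2019/20,15.10.2019,23.07.2020,16.11.2019,31.10.2019,16,15
Czesławice,2019/20,08.10.2019,23.07.2020,24.10.2019,26.10.2019,15,2
Swojczyce,2019/20,17.10.2019,28.07.2020,05.11.2019,26.11.2019,19,11
Wrocław,2019/20,08.10.2019,09.07.2020,14.10.2019,18.10.2019,6,4
Mydlniki,2019/20,06.10.2019,21.07.2020,24.10.2019,24.10.2019,18,0
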