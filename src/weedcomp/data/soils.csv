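site_id,latitude,longitude,sand_pct,silt_pct,clay_pct,texture_printed,n_pct,p_mgkg,k_mgkg,om_pct,ph
Lipnik,53°34′ N,14°95′ E,85.4,14.0,0.6,loamy sand,0.11,232,301,2.2,6.4
Mochełek,53°20′ N,17°86′ E,84.7,14.3,1.1,loamy sand,0.17,238,296,2.6,6.6
Winna Góra,52°12′ N,17°26′ E,70.4,26.3,3.4,sandy loam,,137,162,1.1,5.5
Czesławice,51°18′ N,22°16′ E,15.8,72.6,11.6,silt loam,0.12,158,196,1.5,6.4
Swojczyce,51°06′ N,17°08′ E,66.0,26.0,8.0,sandy loam,0.51,128,125,1.2,6.5
Wrocław,51°04′ N,17°02′ E,56.0,23.0,21.0,sandy clay loam,0.70,182,197,1.2,6.2
Mydlniki,50°07′ N,19°84′ E,39.0,52.0,9.0,silt loam,0.07,173,196,1.1,6.3
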