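predator_id,family,guild,size_limited,N,P_ornata,P_vermiculosa,P_aurea,P_ammon,P_erato,M_piliventris,M_tepperi,C_aeneopilosus,E_aurata,D_cephalotes,D_nigricans,M_erythrocephala,M_luctuosa
Eulamprus quoyii,Scincidae,visual,0,50,0,0,0,0,0,0,0,0,0,0,0,0,0
Manorina melanocephala,Meliphagidae,visual,0,48,0,0,0,0,0,0,0,0.02,0,0,0,0.04,0
Sandalodes superbus,Salticidae,visual,0,37,0,0,0,0,0,0,0,0,0,0,0,0,0
Holoplatys planissima,Salticidae,visual,0,12,0,0,0,0,0,0,0,0,0,0,0,0,0
Ocrisiona sp.,Salticidae,visual,0,26,0,0,0,0,0,0,0,0,0,0,0,3.8,3.8
Servaea incana,Salticidae,ant_eating,0,114,0,0,0,0,0,0,0,0,0,0,0,0,1.8
Euryopis umbilicata,Theridiidae,ant_eating,0,101,0,0,0,0,0,0,0,0,0,0,0,9.9,8.6
Euryopis sp.,Theridiidae,ant_eating,0,12,0,0,0,0,0,0,0,0,0,0,0,0,0
Hemicloea sp. 1,Gnaphosidae,ant_eating,0,20,0,0,0,0,0,0,0,5.0,0,0,0,0,0
Hemicloea sp. 2,Gnaphosidae,ant_eating,0,42,0,0,0,0,0,0,0,2.4,0,0,0,2.4,2.4
Lampona murina,Lamponidae,non_visual,1,46,0,0,0,0,0,0,0,0,0,0,0,2.2,4.3
Clubionia robusta,Clubionidae,non_visual,0,58,0,0,0,0,0,0,0,0,0,0,0,0,1.7
Clubiona sp.,Clubionidae,non_visual,0,85,0,0,0,0,0,0,0,0,0,0,0,2.4,2.4
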