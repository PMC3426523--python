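EC50_CNG:
- 0.42271784257036443
- 6.763485481125831
E_leak:
- -35.27672159515285
- -27.276721595152846
Ef_CaX:
- 0.0390779235106905
- 0.625246776171048
K_CaX:
- 0.03276573245721272
- 0.5242517193154035
K_CaX_mod:
- 0.0019168019083145142
- 0.030668830533032227
K_GTPsupp:
- 0.011315046894590801
- 0.18104075031345282
K_cat_GCY:
- 0.003505709924252148
- 0.05609135878803437
K_cat_GCYGCAPa:
- 1.3566368332755139
- 21.706189332408222
K_cat_GCYGCAPb:
- 1.4051424997773823
- 22.482279996438116
K_cat_PDE:
- 0.0031380402838067914
- 0.05020864454090866
K_m1_CaMCa2_Ca:
- 0.7460455176512766
- 11.936728282420425
K_m1_CaMCa3_Ca:
- 0.05168235608652249
- 0.8269176973843598
K_m1_CaMCa_Ca:
- 3.009041960599558
- 48.14467136959293
K_m1_CaM_Ca:
- 5.503828453062449
- 88.06125524899919
K_m1_GCAPa_Ca:
- 0.0067794066719244666
- 0.10847050675079146
K_m1_GCAPb_Ca:
- 0.0001
- 0.0012606279236817139
K_m1_GCYGCAPa_GTP:
- 0.117560601120786
- 1.880969617932576
K_m1_GCYGCAPb_GTP:
- 0.28169585479704284
- 4.5071336767526855
K_m1_GCY_GCAPa:
- 0.060191744930891744
- 0.9630679188942679
K_m1_GCY_GCAPb:
- 0.09061984121834354
- 1.4499174594934967
K_m1_GCY_GTP:
- 0.055396119985789805
- 0.8863379197726369
K_m1_GTPsupp:
- 0.007947329635287428
- 0.12715727416459885
K_m1_Ga:
- 1.9320044804555285
- 30.912071687288456
K_m1_Ga_GCY:
- 4.957194035139338
- 79.31510456222941
K_m1_Ga_GCYGCAPa:
- 0.09567965274981252
- 1.5308744439970003
K_m1_Ga_GCYGCAPb:
- 0.2395005613834255
- 3.832008982134808
K_m1_PDE_CaMCa4:
- 0.20742896239813416
- 3.3188633983701465
K_m1_PDE_cGMP:
- 0.23274288268459192
- 3.7238861229534708
K_m1_PDEa_cGMP:
- 0.10280037012634251
- 1.6448059220214801
K_m1_odor_R:
- 3.899120461406402
- 62.38592738250243
K_p1_CaMCa2_Ca:
- 2.1709897178576494
- 34.73583548572239
K_p1_CaMCa3_Ca:
- 6.116836776978227
- 97.86938843165163
K_p1_CaMCa_Ca:
- 3.956102553864757
- 63.297640861836115
K_p1_CaM_Ca:
- 0.7851238269855617
- 12.561981231768987
K_p1_GCAPa_Ca:
- 5.633639434270413
- 90.13823094832661
K_p1_GCAPb_Ca:
- 0.29221311332273564
- 4.67540981316377
K_p1_GCYGCAPa_GTP:
- 0.19943414926286862
- 3.190946388205898
K_p1_GCYGCAPb_GTP:
- 0.7542737493113671
- 12.068379988981874
K_p1_GCY_GCAPa:
- 0.002342933325852132
- 0.03748693321363411
K_p1_GCY_GCAPb:
- 0.016193807381479894
- 0.2591009181036783
K_p1_GCY_GTP:
- 0.01
- 0.12120451419251142
K_p1_Ga_GCY:
- 0.3293733348996579
- 5.269973358394527
K_p1_Ga_GCYGCAPa:
- 54.99268362217745
- 500.0
K_p1_Ga_GCYGCAPb:
- 65.9428875965039
- 500.0
K_p1_PDE_CaMCa4:
- 0.23919472315962473
- 3.8271155705539956
K_p1_PDE_cGMP:
- 0.040437967175383595
- 0.6470074748061375
K_p1_PDEa_cGMP:
- 1.7086180352257183
- 27.337888563611493
K_p1_PDEactive:
- 3.673293563034868
- 58.77269700855789
K_p1_R_Ga:
- 4.359019874529248
- 69.74431799246797
K_p1_odor_R:
- 0.4094570769943404
- 6.551313231909447
g_CNG_max:
- 5.511593458804872
- 88.18549534087795
g_VDCC_max:
- 0.34998001642986093
- 5.599680262877775
g_leak:
- 0.2620940543905341
- 4.193504870248546
gc_CNG:
- 0.7244862042609278
- 11.591779268174845
gc_VDCC:
- 0.1
- 1.6
m_CaX:
- 1.0
- 8.0
n_CNG:
- 1.5
- 4.0
n_CaX:
- 1.5
- 3.0
total_CaM:
- 3.104035957167559
- 10.0
total_GCAPa:
- 0.40164775392426466
- 1.6065910156970586
total_GCAPb:
- 1.5514239012252637
- 6.205695604901055
total_GCY:
- 0.622346237692729
- 2.489384950770916
total_Ga:
- 0.7585163558449705
- 3.034065423379882
total_PDE:
- 0.12597600760562713
- 0.5039040304225085
total_R:
- 0.3420920741139552
- 1.3683682964558208
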