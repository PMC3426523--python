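K_p1_odor_R: 1.6378283079773617
K_m1_odor_R: 15.596481845625608
K_p1_R_Ga: 17.436079498116992
K_m1_Ga: 7.728017921822114
K_p1_Ga_GCY: 1.3174933395986317
K_m1_Ga_GCY: 19.828776140557352
K_p1_Ga_GCYGCAPa: 219.9707344887098
K_m1_Ga_GCYGCAPa: 0.3827186109992501
K_p1_Ga_GCYGCAPb: 263.7715503860156
K_m1_Ga_GCYGCAPb: 0.958002245533702
K_p1_GCY_GTP: 0.030301128548127856
K_m1_GCY_GTP: 0.22158447994315922
K_cat_GCY: 0.014022839697008592
K_p1_GCYGCAPa_GTP: 0.7977365970514745
K_m1_GCYGCAPa_GTP: 0.470242404483144
K_cat_GCYGCAPa: 5.4265473331020555
K_p1_GCYGCAPb_GTP: 3.0170949972454686
K_m1_GCYGCAPb_GTP: 1.1267834191881714
K_cat_GCYGCAPb: 5.620569999109529
K_GTPsupp: 0.045260187578363205
K_m1_GTPsupp: 0.03178931854114971
K_p1_PDE_cGMP: 0.16175186870153438
K_m1_PDE_cGMP: 0.9309715307383677
K_cat_PDE: 0.012552161135227165
K_p1_PDEa_cGMP: 6.834472140902873
K_m1_PDEa_cGMP: 0.41120148050537003
K_p1_PDEactive: 14.693174252139473
K_p1_CaM_Ca: 3.140495307942247
K_m1_CaM_Ca: 22.015313812249797
K_p1_CaMCa_Ca: 15.824410215459029
K_m1_CaMCa_Ca: 12.036167842398232
K_p1_CaMCa2_Ca: 8.683958871430598
K_m1_CaMCa2_Ca: 2.9841820706051063
K_p1_CaMCa3_Ca: 24.467347107912907
K_m1_CaMCa3_Ca: 0.20672942434608996
K_p1_PDE_CaMCa4: 0.9567788926384989
K_m1_PDE_CaMCa4: 0.8297158495925366
K_p1_GCAPa_Ca: 22.534557737081652
K_m1_GCAPa_Ca: 0.027117626687697866
K_p1_GCAPb_Ca: 1.1688524532909426
K_m1_GCAPb_Ca: 0.00031515698092042846
K_p1_GCY_GCAPa: 0.009371733303408528
K_m1_GCY_GCAPa: 0.24076697972356698
K_p1_GCY_GCAPb: 0.06477522952591958
K_m1_GCY_GCAPb: 0.3624793648733742
total_R: 0.6841841482279104
total_Ga: 1.517032711689941
total_GCY: 1.244692475385458
total_GCAPa: 0.8032955078485293
total_GCAPb: 3.1028478024505275
total_PDE: 0.25195201521125427
total_CaM: 6.208071914335118
EC50_CNG: 1.6908713702814577
n_CNG: 1.9672454576139502
g_CNG_max: 22.046373835219487
E_CNG: 10.0
g_VDCC_max: 1.3999200657194437
V_half: -10.0
s_V: 6.0
E_Ca: 60.0
gc_CNG: 2.897944817043711
gc_VDCC: 0.4
g_leak: 1.0483762175621365
E_leak: -31.276721595152846
C_m: 1.0
alpha_conv: 1.0
Ef_CaX: 0.156311694042762
K_CaX: 0.13106292982885087
n_CaX: 2.447001454926693
m_CaX: 5.0706217979485455
K_CaX_mod: 0.007667207633258057
EC50_GCaMP: 0.235
n_GCaMP: 3.3
F_min: 1.0
F_max: 5.5
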