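subject_id,group,burden_h_per_day,graft_pct_scar,graft_pct_lv,pre_freeze_ctnt_pct,cm_sirpa_cd90neg,cm_cd200neg,cm_cd200pos,committed_vcm,mesoderm_cd13,fibroblast_cd90,endothelial,nonmyocyte_unspecified
PSC-CM1,PSC-CM,15.0,19.8,1.9,64,68.2,33.0,35.2,1.3,3.0,0.5,0.0,26.9
PSC-CM2,PSC-CM,2.4,N/A,N/A,71,41.5,41.5,0.0,1.5,31.5,0.0,0.0,25.5
PSC-CM3,PSC-CM,5.8,37.2,3.8,73,50.6,47.9,2.7,1.7,1.3,6.8,0.2,39.4
PSC-CM4,PSC-CM,4.7,3.5,0.4,84,66.3,42.9,23.4,2.7,17.1,0.7,0.2,13.0
PSC-CM5,PSC-CM,15.7,3.0,0.3,85,N/A,N/A,N/A,N/A,N/A,N/A,N/A,N/A
PSC-CM+AA1,PSC-CM+AA,1.1,15.8,2.0,70,87.1,13.8,73.3,0.2,1.9,0.0,0.2,10.6
PSC-CM+AA2,PSC-CM+AA,0.8,42.5,3.8,85,64.6,59.7,4.9,0.9,14.6,0.5,0.1,19.3
PSC-CM+AA3,PSC-CM+AA,0.7,2.7,0.4,90,76.5,65.6,10.9,1.0,12.1,0.6,0.1,9.7
PSC-CM+AA4,PSC-CM+AA,2.2,N/A,N/A,77,32.4,28.2,4.2,0.0,46.5,1.1,0.4,19.5
PSC-CM+AA5,PSC-CM+AA,0.2,16.2,0.3,84,N/A,N/A,N/A,N/A,N/A,N/A,N/A,N/A
PSC-CM+CA1,PSC-CM+CA,1.5,N/A,N/A,58,46.2,37.3,8.9,0.3,0.9,2.8,0.5,49.3
PSC-CM+CA2,PSC-CM+CA,0.7,N/A,N/A,90,81.1,60.9,20.3,0.0,4.9,0.5,1.0,12.5
PSC-CM+CA3,PSC-CM+CA,14.2,N/A,N/A,63,N/A,N/A,N/A,N/A,N/A,N/A,N/A,N/A
RA-PSC-CM1,RA-PSC-CM,17.7,8.1,0.6,72,46.9,1.8,45.1,0.0,3.0,20.9,0.4,28.7
RA-PSC-CM2,RA-PSC-CM,14.8,N/A,N/A,68,44.5,0.7,43.8,0.0,3.4,1.5,0.1,50.5
RA-PSC-CM3,RA-PSC-CM,14.0,10.7,2.0,60,52.0,1.1,50.9,2.0,36.8,4.4,0.2,4.7
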