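arvc_diagnosis,tfc_major,tfc_minor,cmr_major,cmr_minor,vt_vf,icd,cardiac_arrest,syncope,ecg_major,sa_ecg,fat,fibrosis
1,1,0,0,0,0,0,0,0,0,0,0,1
1,1,0,0,0,0,0,0,1,0,0,0,0
3,2,0,0,0,1,1,1,1,0,0,0,0
3,1,2,0,1,1,0,0,0,0,1,1,1
3,2,2,1,0,0,0,0,0,1,1,0,1
3,2,1,1,0,0,0,0,0,0,0,0,0
3,2,1,1,0,1,0,0,1,1,0,0,0
3,5,1,0,1,1,1,1,1,1,1,0,0
1,1,0,0,0,0,0,0,0,0,0,0,0
1,1,0,0,0,0,0,0,0,0,0,0,0
1,1,0,0,0,0,0,0,0,0,0,0,0
3,2,0,1,0,1,1,1,1,0,0,0,1
2,1,1,0,0,0,0,0,0,0,1,0,0
3,2,1,0,0,1,1,1,1,0,1,0,0
3,4,1,1,0,1,1,0,0,1,1,0,0
3,5,0,1,0,1,1,0,0,1,1,0,1
3,4,1,1,0,1,1,0,0,1,1,0,1
3,2,1,0,0,1,0,0,1,1,0,0,0
3,5,0,1,0,1,1,0,1,1,1,0,0
3,2,0,0,0,0,0,0,0,1,0,0,0
3,1,2,0,0,0,0,0,0,1,0,0,0
1,1,0,0,0,0,0,0,0,0,0,0,0
1,1,0,0,0,0,0,0,0,0,1,0,0
1,1,0,0,0,0,0,0,0,0,0,0,0
3,3,1,1,0,1,0,0,0,1,0,0,0
3,2,0,1,0,0,0,0,0,1,0,0,0
2,1,1,1,0,0,0,0,0,0,1,1,0
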