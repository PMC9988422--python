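substrate,transporter,experiment,pe_a2b,pe_b2a,mark
rhodamine123,P-gp,E1,24.5,127.5,*
rhodamine123,P-gp,E2,11.6,21.7,**
rhodamine123,P-gp,E3,35.3,33.0,none
rhodamine123,P-gp,E4,21.6,20.1,none
hoechst33342,BCRP,E1,20.3,37.0,*
hoechst33342,BCRP,E2,8.4,12.6,none
hoechst33342,BCRP,E3,1.4,3.6,*
hoechst33342,BCRP,E4,2.4,15.6,*
2-NBDG,Glut1,E1,56.5,90.8,none
2-NBDG,Glut1,E2,113.5,114.3,none
2-NBDG,Glut1,E3,51.9,37.9,*
2-NBDG,Glut1,E4,44.8,45.1,none
transferrin,TfR,E1,1.3,1.2,none
transferrin,TfR,E2,3.5,1.8,**
transferrin,TfR,E3,3.0,1.7,*
digoxin,P-gp,E1,41.2,52.9,*
digoxin,P-gp,E2,45.7,53.6,none
digoxin,P-gp,E3,48.9,55.5,none
digoxin,P-gp,E4,17.6,28.1,**
dantrolene,BCRP,E1,62.9,92.5,**
dantrolene,BCRP,E2,135.5,368.9,*
dantrolene,BCRP,E3,98.5,330.4,*
dantrolene,BCRP,E4,107.3,166.9,none
SASP,BCRP,E1,40.2,50.1,**
SASP,BCRP,E2,81.2,84.4,*
SASP,BCRP,E3,58.8,101.3,**
SASP,BCRP,E4,25.7,36.4,**
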