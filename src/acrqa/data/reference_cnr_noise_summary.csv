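modality,machine,protocol,metric,mean,sd
CT,CTSIM,Brain,cnr_polyethylene,24.8,1.2
CT,CTSIM,SRS Brain,cnr_polyethylene,14.5,0.4
CT,CTSIM,Pelvis,cnr_polyethylene,21.2,0.7
CT,CTSIM,Chest,cnr_polyethylene,19.1,0.9
CT,CTSIM,ENT,cnr_polyethylene,20.0,0.8
CT,CTSIM,Brain,cnr_acrylic,33.2,1.6
CT,CTSIM,SRS Brain,cnr_acrylic,19.4,0.5
CT,CTSIM,Pelvis,cnr_acrylic,28.1,0.8
CT,CTSIM,Chest,cnr_acrylic,25.3,1.1
CT,CTSIM,ENT,cnr_acrylic,26.8,1.0
CT,CTSIM,Brain,noise_polyethylene,0.35,0.02
CT,CTSIM,SRS Brain,noise_polyethylene,0.60,0.03
CT,CTSIM,Pelvis,noise_polyethylene,0.41,0.03
CT,CTSIM,Chest,noise_polyethylene,0.45,0.03
CT,CTSIM,ENT,noise_polyethylene,0.42,0.02
CT,CTSIM,Brain,noise_acrylic,0.30,0.01
CT,CTSIM,SRS Brain,noise_acrylic,0.52,0.02
CT,CTSIM,Pelvis,noise_acrylic,0.37,0.03
CT,CTSIM,Chest,noise_acrylic,0.41,0.02
CT,CTSIM,ENT,noise_acrylic,0.37,0.01
CBCT,Novalis,Std. Dose Head,cnr_polyethylene,3.4,0.1
CBCT,Novalis,Hi-quality Head,cnr_polyethylene,7.4,0.2
CBCT,Novalis,Low-dose Head,cnr_polyethylene,4.2,1.8
CBCT,Novalis,Low-dose Thorax,cnr_polyethylene,11.8,0.6
CBCT,Novalis,Pelvis,cnr_polyethylene,12.1,1.1
CBCT,Novalis,Std. Dose Head,cnr_acrylic,3.5,0.0
CBCT,Novalis,Hi-quality Head,cnr_acrylic,7.5,0.3
CBCT,Novalis,Low-dose Head,cnr_acrylic,4.2,1.6
CBCT,Novalis,Low-dose Thorax,cnr_acrylic,12.9,0.9
CBCT,Novalis,Pelvis,cnr_acrylic,14.2,1.2
CBCT,21EX-A,Std. Dose Head,cnr_polyethylene,4.0,0.3
CBCT,21EX-A,Hi-quality Head,cnr_polyethylene,7.3,0.4
CBCT,21EX-A,Low-dose Head,cnr_polyethylene,4.3,0.2
CBCT,21EX-A,Low-dose Thorax,cnr_polyethylene,10.4,0.7
CBCT,21EX-A,Pelvis,cnr_polyethylene,10.0,1.3
CBCT,21EX-A,Std. Dose Head,cnr_acrylic,3.2,0.2
CBCT,21EX-A,Hi-quality Head,cnr_acrylic,6.0,0.4
CBCT,21EX-A,Low-dose Head,cnr_acrylic,3.4,0.2
CBCT,21EX-A,Low-dose Thorax,cnr_acrylic,10.7,1.1
CBCT,21EX-A,Pelvis,cnr_acrylic,11.0,1.5
CBCT,21EX-B,Std. Dose Head,cnr_polyethylene,3.7,0.2
CBCT,21EX-B,Hi-quality Head,cnr_polyethylene,6.6,0.3
CBCT,21EX-B,Low-dose Head,cnr_polyethylene,4.0,0.6
CBCT,21EX-B,Low-dose Thorax,cnr_polyethylene,9.9,0.3
CBCT,21EX-B,Pelvis,cnr_polyethylene,9.3,0.4
CBCT,21EX-B,Std. Dose Head,cnr_acrylic,3.3,0.1
CBCT,21EX-B,Hi-quality Head,cnr_acrylic,6.1,0.3
CBCT,21EX-B,Low-dose Head,cnr_acrylic,3.7,0.6
CBCT,21EX-B,Low-dose Thorax,cnr_acrylic,9.3,0.4
CBCT,21EX-B,Pelvis,cnr_acrylic,9.3,0.2
CBCT,Novalis,Std. Dose Head,noise_polyethylene,3.5,0.11
CBCT,Novalis,Hi-quality Head,noise_polyethylene,1.9,0.08
CBCT,Novalis,Low-dose Head,noise_polyethylene,3.7,0.06
CBCT,Novalis,Low-dose Thorax,noise_polyethylene,1.04,0.06
CBCT,Novalis,Pelvis,noise_polyethylene,0.87,0.07
CBCT,Novalis,Std. Dose Head,noise_acrylic,3.2,0.06
CBCT,Novalis,Hi-quality Head,noise_acrylic,1.5,0.05
CBCT,Novalis,Low-dose Head,noise_acrylic,3.1,0.09
CBCT,Novalis,Low-dose Thorax,noise_acrylic,1.05,0.08
CBCT,Novalis,Pelvis,noise_acrylic,0.9,0.06
CBCT,21EX-A,Std. Dose Head,noise_polyethylene,3.9,0.20
CBCT,21EX-A,Hi-quality Head,noise_polyethylene,2.7,0.29
CBCT,21EX-A,Low-dose Head,noise_polyethylene,4.2,0.37
CBCT,21EX-A,Low-dose Thorax,noise_polyethylene,1.0,0.07
CBCT,21EX-A,Pelvis,noise_polyethylene,1.10,0.07
CBCT,21EX-A,Std. Dose Head,noise_acrylic,3.3,0.14
CBCT,21EX-A,Hi-quality Head,noise_acrylic,1.9,0.09
CBCT,21EX-A,Low-dose Head,noise_acrylic,3.3,0.43
CBCT,21EX-A,Low-dose Thorax,noise_acrylic,1.09,0.07
CBCT,21EX-A,Pelvis,noise_acrylic,1.0,0.08
CBCT,21EX-B,Std. Dose Head,noise_polyethylene,3.7,0.09
CBCT,21EX-B,Hi-quality Head,noise_polyethylene,2.0,0.10
CBCT,21EX-B,Low-dose Head,noise_polyethylene,3.3,0.42
CBCT,21EX-B,Low-dose Thorax,noise_polyethylene,1.1,0.04
CBCT,21EX-B,Pelvis,noise_polyethylene,1.14,0.05
CBCT,21EX-B,Std. Dose Head,noise_acrylic,3.4,0.18
CBCT,21EX-B,Hi-quality Head,noise_acrylic,1.7,0.10
CBCT,21EX-B,Low-dose Head,noise_acrylic,3.1,0.40
CBCT,21EX-B,Low-dose Thorax,noise_acrylic,1.21,0.06
CBCT,21EX-B,Pelvis,noise_acrylic,1.1,0.05
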