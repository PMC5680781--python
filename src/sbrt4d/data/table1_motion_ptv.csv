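# Motion and PTV-size cohort: 12 consecutive pancreatic SBRT patients.
# Transcribed per-patient planning target volumes for the motion-envelope
# (ITV) and tumor-tracking concepts (cm^3), respiratory-induced peak-to-peak
# motion amplitudes per axis (mm), and the published 3D motion magnitude
# (mm). The per-axis columns are authoritative; the 3D column is recomputed
# and cross-checked at one decimal place on load.
patient,ptv_itv_cc,ptv_track_cc,ap_mm,si_mm,lr_mm,motion3d_mm
1,54.3,33.0,2.4,10.4,3.3,11.2
2,146.2,122.4,3.0,5.1,0.6,5.9
3,236.7,200.9,2.0,4.3,1.6,5.1
4,109.8,90.2,1.0,3.7,0.7,3.9
5,154.9,147.6,0.7,1.1,0.3,1.3
6,34.9,28.2,0.5,4.6,1.1,4.7
7,83.0,70.6,1.0,1.6,0.8,2.1
8,114.6,90.4,6.1,1.9,1.7,6.6
9,241.4,209.6,1.8,7.6,1.2,7.8
10,244.0,208.4,1.9,4.3,0.3,4.8
11,177.6,163.9,1.3,5.0,0.5,5.2
12,116.3,95.5,2.1,7.4,3.5,8.5
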