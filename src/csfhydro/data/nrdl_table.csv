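level,side,dorsal_RL_mm,dorsal_theta_deg,dorsal_thickness_mm,ventral_RL_mm,ventral_theta_deg,ventral_thickness_mm
C1,left,3.8,-0.9,0.65,8.9,-0.9,1.7
C1,right,4.7,-1.8,0.65,7.9,-1.8,1.6
C2,left,8.0,-17.1,0.70,12.3,-17.1,1.6
C2,right,7.4,-18.2,0.70,12.6,-18.2,1.8
C3,left,12.1,-43.4,0.73,11.6,-43.4,1.7
C3,right,11.2,-39.4,0.73,12.1,-39.4,1.7
C4,left,12.3,-44.4,0.75,12.1,-44.4,1.7
C4,right,12.7,-38.6,0.75,12.3,-38.6,1.8
C5,left,12.5,-42.9,0.81,13.1,-42.9,2.0
C5,right,12.1,-37.7,0.81,13.4,-37.7,1.9
C6,left,11.8,-44.5,0.90,13.5,-44.5,1.9
C6,right,12.3,-41.5,0.90,13.5,-41.5,1.9
C7,left,11.6,-51.6,0.98,12.0,-51.6,1.9
C7,right,11.4,-47.6,0.98,12.4,-47.6,2.0
C8,left,11.2,-58.5,0.89,11.1,-58.5,1.9
C8,right,10.8,-55.9,0.89,11.1,-55.9,1.9
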