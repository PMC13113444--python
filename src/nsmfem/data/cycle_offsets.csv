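# Per-muscle active-force cycle offsets (percent of gait cycle) observed for
# each walking condition: elderly stroke patients at free speed (ESP_free) and
# elderly subjects with no lower-limb disease at four speeds (ESND_R_fast,
# ESND_free, ESND_slow, ESND_X_slow).
muscle,ESP_free,ESND_R_fast,ESND_free,ESND_slow,ESND_X_slow
Glut_Max1,11.2,15,17.49,16.15,16.03
TFL,0,5,1.94,0,0
Iliacus,9.27,1.25,0,0,0
Pectineus,4.76,1.25,1.46,0,0
Vas_Int,30.2,42.5,39.84,7.43,3.11
Med_Gas,3.91,7.5,1,0,0
Tib_Ant,18.4,2.75,3.33,0,3.79
Tib_Post,14.5,11.25,6.32,8.1,0.38
Soleus,0,8.75,1.46,5.43,0.32
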