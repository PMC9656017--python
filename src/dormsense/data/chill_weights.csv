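# Stepwise chill-unit weight tables, one row per temperature bin.
# Bins are half-open [t_low_C, t_high_C); -inf/inf allowed.
# chilling_hours: Weinberger 1950 (hours in the 0-7.2 C band).
# utah: Richardson et al. 1974 (the tested reference table).
# low_chill: Gilreath & Buchanan 1981 (transcribed from the published breakpoints).
# north_carolina: Shaltout & Unrath 1983 (transcribed from the published breakpoints).
model,t_low_C,t_high_C,weight
chilling_hours,-inf,0.0,0.0
chilling_hours,0.0,7.2,1.0
chilling_hours,7.2,inf,0.0
utah,-inf,1.4,0.0
utah,1.4,2.4,0.5
utah,2.4,9.1,1.0
utah,9.1,12.4,0.5
utah,12.4,15.9,0.0
utah,15.9,18.0,-0.5
utah,18.0,inf,-1.0
low_chill,-inf,-1.1,0.0
low_chill,-1.1,1.7,0.5
low_chill,1.7,7.3,1.0
low_chill,7.3,13.1,0.5
low_chill,13.1,16.5,0.0
low_chill,16.5,19.5,-0.5
low_chill,19.5,inf,-1.0
north_carolina,-inf,-1.1,0.0
north_carolina,-1.1,1.6,0.5
north_carolina,1.6,7.2,1.0
north_carolina,7.2,13.0,0.5
north_carolina,13.0,16.5,0.0
north_carolina,16.5,19.0,-0.5
north_carolina,19.0,20.7,-1.0
north_carolina,20.7,22.1,-1.5
north_carolina,22.1,inf,-2.0
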