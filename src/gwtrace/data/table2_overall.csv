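well_id,area,analyte,mean_ugL,sd_ugL,min_ugL,max_ugL
GW1,residential,arsenic,0,0,0,0
GW1,residential,antimony,19.0,21.2,0,45.0
GW1,residential,selenium,21.2,19.6,2.0,43.0
GW2,residential,arsenic,0,0,0,0
GW2,residential,antimony,28.0,15.3,10.0,46.0
GW2,residential,selenium,20.7,19.3,1.0,32.0
GW3,residential,arsenic,0,0,0,0
GW3,residential,antimony,25.8,29.8,0,67.0
GW3,residential,selenium,12.8,11.4,0,26.0
GW4,residential,arsenic,6.67,8.48,0,21.0
GW4,residential,antimony,28.8,25.2,0,66.0
GW4,residential,selenium,28.7,21.1,4.0,53.0
GW5,residential,arsenic,0,0,0,0
GW5,residential,antimony,21.8,20.5,0,44.0
GW5,residential,selenium,16.7,14.7,2.0,34.0
GW6,residential,arsenic,2.17,3.49,0,8.0
GW6,residential,antimony,28.8,31.7,0,63.0
GW6,residential,selenium,11.3,7.9,3.0,21.0
GW7,residential,arsenic,0,0,0,0
GW7,residential,antimony,13.5,15.1,0,32.0
GW7,residential,selenium,8.50,6.5,0,14.0
GW8,residential,arsenic,0,0,0,0
GW8,residential,antimony,19.7,25.0,0,61.0
GW8,residential,selenium,7.33,6.22,0,15.0
GW9,residential,arsenic,0,0,0,0
GW9,residential,antimony,20.8,23.8,0,54.0
GW9,residential,selenium,44.7,16.8,26.0,74.0
GW10,residential,arsenic,0,0,0,0
GW10,residential,antimony,18.8,22.6,0,54.0
GW10,residential,selenium,31.7,4.0,24.0,36.0
GW11,residential,arsenic,0,0,0,0
GW11,residential,antimony,28.3,24.6,0,65.0
GW11,residential,selenium,20.5,9.7,8.0,33.0
GW12,residential,arsenic,0,0,0,0
GW12,residential,antimony,33.2,36.8,0,76.0
GW12,residential,selenium,30.3,25.5,4.0,58.0
GW13,residential,arsenic,0,0,0,0
GW13,residential,antimony,27.5,30.6,0,63.0
GW13,residential,selenium,14.3,7.9,4.0,23.0
GW14,residential,arsenic,0,0,0,0
GW14,residential,antimony,15.2,19.2,0,47.0
GW14,residential,selenium,16.5,6.2,9.0,25.0
GW15,residential,arsenic,0,0,0,0
GW15,residential,antimony,32.8,23.5,5.0,56.0
GW15,residential,selenium,29.0,10.1,17.0,43.0
GW16,residential,arsenic,6.67,7.47,0,16.0
GW16,residential,antimony,38.7,34.9,10.0,76.0
GW16,residential,selenium,9.17,5.2,0,16.0
GW17,residential,arsenic,0,0,0,0
GW17,residential,antimony,24.0,23.1,0,52.0
GW17,residential,selenium,7.83,5.1,0,14.0
GW18,residential,arsenic,0,0,0,0
GW18,residential,antimony,20.2,23.3,0,44.0
GW18,residential,selenium,46.3,22.4,23.0,73.0
GW19,residential,arsenic,0,0,0,0
GW19,residential,antimony,13.5,15.0,0,31.0
GW19,residential,selenium,11.8,6.5,10.0,16.0
GW20,residential,arsenic,0,0,0,0
GW20,residential,antimony,23.2,26.0,0,54.0
GW20,residential,selenium,20.2,10.9,6.0,33.0
GW21,residential,arsenic,0,0,0,0
GW21,residential,antimony,19.5,23.1,0,55.0
GW21,residential,selenium,37.5,20.4,16.0,64.0
GW22,residential,arsenic,0,0,0,0
GW22,residential,antimony,29.2,32.1,0,62.0
GW22,residential,selenium,41.5,23.2,17.0,66.0
GW23,residential,arsenic,0,0,0,0
GW23,residential,antimony,29.8,32.8,0,63.0
GW23,residential,selenium,20.2,12.7,3.0,35.0
GW24,residential,arsenic,0,0,0,0
GW24,residential,antimony,29.0,31.9,0,63.0
GW24,residential,selenium,29.7,13.9,16.0,44.0
GW25,commercial,arsenic,33.8,37.2,0,73.0
GW25,commercial,antimony,28.3,31.2,0,62.0
GW25,commercial,selenium,31.3,8.1,21.0,41.0
GW26,commercial,arsenic,25.3,28.1,0,57.0
GW26,commercial,antimony,28.5,31.5,0,64.0
GW26,commercial,selenium,44.5,10.8,33.0,58.0
GW27,commercial,arsenic,0,0,0,0
GW27,commercial,antimony,18.2,20.6,0,44.0
GW27,commercial,selenium,24.5,17.8,7.0,46.0
GW28,commercial,arsenic,0,0,0,0
GW28,commercial,antimony,26.3,29.2,0,61.0
GW28,commercial,selenium,25.7,20.7,5.0,53.0
GW29,commercial,arsenic,0,0,0,0
GW29,commercial,antimony,17.8,20.0,0,43.0
GW29,commercial,selenium,27.3,17.9,8.0,51.0
GW30,industrial,arsenic,0,0,0,0
GW30,industrial,antimony,26.3,28.9,0,52.0
GW30,industrial,selenium,9.50,9.61,0,23.0
GW31,industrial,arsenic,0,0,0,0
GW31,industrial,antimony,26.8,29.5,0,56.0
GW31,industrial,selenium,16.5,12.5,2.0,33.0
GW32,industrial,arsenic,6.67,8.48,0,21.0
GW32,industrial,antimony,30.3,33.4,0,64.0
GW32,industrial,selenium,16.2,11.8,0,32.0
GW33,industrial,arsenic,0,0,0,0
GW33,industrial,antimony,24.2,26.6,0,52.0
GW33,industrial,selenium,11.2,10.1,0,23.0
GW34,agricultural,arsenic,0,0,0,0
GW34,agricultural,antimony,23.3,25.7,0,51.0
GW34,agricultural,selenium,23.2,5.3,17.0,31.0
GW35,agricultural,arsenic,0,0,0,0
GW35,agricultural,antimony,30.8,33.9,0,66.0
GW35,agricultural,selenium,18.5,5.4,13.0,27.0
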