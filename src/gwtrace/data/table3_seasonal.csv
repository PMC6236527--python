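well_id,area,season,analyte,mean_ugL,sd_ugL
GW1,residential,wet,arsenic,0,0
GW1,residential,wet,selenium,3.67,2.1
GW1,residential,wet,antimony,0,0
GW1,residential,dry,arsenic,0,0
GW1,residential,dry,selenium,38.7,5.9
GW1,residential,dry,antimony,38.0,6.2
GW2,residential,wet,arsenic,0,0
GW2,residential,wet,selenium,3.33,2.1
GW2,residential,wet,antimony,15.0,6.2
GW2,residential,dry,arsenic,0,0
GW2,residential,dry,selenium,38.0,5.3
GW2,residential,dry,antimony,41.0,6.2
GW3,residential,wet,arsenic,0,0
GW3,residential,wet,selenium,2.67,3.1
GW3,residential,wet,antimony,0,0
GW3,residential,dry,arsenic,0,0
GW3,residential,dry,selenium,23.0,2.6
GW3,residential,dry,antimony,51.7,15.0
GW4,residential,wet,arsenic,0,0
GW4,residential,wet,selenium,10.7,7.6
GW4,residential,wet,antimony,8.0,7.0
GW4,residential,dry,arsenic,13.3,6.8
GW4,residential,dry,selenium,46.7,9.3
GW4,residential,dry,antimony,49.7,15.2
GW5,residential,wet,arsenic,0,0
GW5,residential,wet,selenium,3.67,2.1
GW5,residential,wet,antimony,3.67,6.4
GW5,residential,dry,arsenic,0,0
GW5,residential,dry,selenium,29.6,5.1
GW5,residential,dry,antimony,40.0,4.0
GW6,residential,wet,arsenic,0,0
GW6,residential,wet,selenium,4.33,1.5
GW6,residential,wet,antimony,0,0
GW6,residential,dry,arsenic,4.33,4.0
GW6,residential,dry,selenium,18.3,2.5
GW6,residential,dry,antimony,57.7,5.0
GW7,residential,wet,arsenic,0,0
GW7,residential,wet,selenium,3.0,2.6
GW7,residential,wet,antimony,0,0
GW7,residential,dry,arsenic,0,0
GW7,residential,dry,selenium,14.0,3.0
GW7,residential,dry,antimony,27.0,5.0
GW8,residential,wet,arsenic,0,0
GW8,residential,wet,selenium,2.0,2.6
GW8,residential,wet,antimony,0,0
GW8,residential,dry,arsenic,0,0
GW8,residential,dry,selenium,12.6,2.1
GW8,residential,dry,antimony,39.3,20.0
GW9,residential,wet,arsenic,0,0
GW9,residential,wet,selenium,33.3,8.7
GW9,residential,wet,antimony,0,0
GW9,residential,dry,arsenic,0,0
GW9,residential,dry,selenium,56.0,15.6
GW9,residential,dry,antimony,41.6,10.7
GW10,residential,wet,arsenic,0,0
GW10,residential,wet,selenium,29.7,4.9
GW10,residential,wet,antimony,0,0
GW10,residential,dry,arsenic,0,0
GW10,residential,dry,selenium,33.7,2.1
GW10,residential,dry,antimony,37.7,14.6
GW11,residential,wet,arsenic,0,0
GW11,residential,wet,selenium,12.3,4.5
GW11,residential,wet,antimony,8.0,7.0
GW11,residential,dry,arsenic,0,0
GW11,residential,dry,selenium,28.7,3.8
GW11,residential,dry,antimony,48.7,14.8
GW12,residential,wet,arsenic,0,0
GW12,residential,wet,selenium,7.33,3.5
GW12,residential,wet,antimony,0,0
GW12,residential,dry,arsenic,0,0
GW12,residential,dry,selenium,53.3,5.0
GW12,residential,dry,antimony,66.3,9.5
GW13,residential,wet,arsenic,0,0
GW13,residential,wet,selenium,8.0,5.3
GW13,residential,wet,antimony,0,0
GW13,residential,dry,arsenic,0,0
GW13,residential,dry,selenium,20.7,3.2
GW13,residential,dry,antimony,55.0,8.5
GW14,residential,wet,arsenic,0,0
GW14,residential,wet,selenium,11.3,2.1
GW14,residential,wet,antimony,0,0
GW14,residential,dry,arsenic,0,0
GW14,residential,dry,selenium,21.6,3.5
GW14,residential,dry,antimony,30.3,8.5
GW15,residential,wet,arsenic,0,0
GW15,residential,wet,selenium,20.3,3.1
GW15,residential,wet,antimony,11.7,5.9
GW15,residential,dry,arsenic,0,0
GW15,residential,dry,selenium,37.6,4.7
GW15,residential,dry,antimony,54.0,2.6
GW16,residential,wet,arsenic,0,0
GW16,residential,wet,selenium,6.0,5.3
GW16,residential,wet,antimony,7.33,6.4
GW16,residential,dry,arsenic,13.3,2.5
GW16,residential,dry,selenium,12.3,3.2
GW16,residential,dry,antimony,70.0,7.9
GW17,residential,wet,arsenic,0,0
GW17,residential,wet,selenium,4.0,4.0
GW17,residential,wet,antimony,3.67,4.0
GW17,residential,dry,arsenic,0,0
GW17,residential,dry,selenium,11.7,2.1
GW17,residential,dry,antimony,44.3,8.6
GW18,residential,wet,arsenic,0,0
GW18,residential,wet,selenium,26.7,5.5
GW18,residential,wet,antimony,0,0
GW18,residential,dry,arsenic,0,0
GW18,residential,dry,selenium,66.0,8.2
GW18,residential,dry,antimony,40.3,11.9
GW19,residential,wet,arsenic,0,0
GW19,residential,wet,selenium,6.67,4.2
GW19,residential,wet,antimony,0,0
GW19,residential,dry,arsenic,0,0
GW19,residential,dry,selenium,17.0,2.6
GW19,residential,dry,antimony,27.0,3.6
GW20,residential,wet,arsenic,0,0
GW20,residential,wet,selenium,11.3,5.0
GW20,residential,wet,antimony,0,0
GW20,residential,dry,arsenic,0,0
GW20,residential,dry,selenium,29.0,6.1
GW20,residential,dry,antimony,46.3,9.3
GW21,residential,wet,arsenic,0,0
GW21,residential,wet,selenium,19.7,4.0
GW21,residential,wet,antimony,0,0
GW21,residential,dry,arsenic,0,0
GW21,residential,dry,selenium,55.3,8.5
GW21,residential,dry,antimony,39.0,14.0
GW22,residential,wet,arsenic,0,0
GW22,residential,wet,selenium,20.7,3.2
GW22,residential,wet,antimony,0,0
GW22,residential,dry,arsenic,0,0
GW22,residential,dry,selenium,62.3,5.5
GW22,residential,dry,antimony,58.3,4.7
GW23,residential,wet,arsenic,0,0
GW23,residential,wet,selenium,9.33,6.0
GW23,residential,wet,antimony,0,0
GW23,residential,dry,arsenic,0,0
GW23,residential,dry,selenium,31.0,4.0
GW23,residential,dry,antimony,59.7,4.2
GW24,residential,wet,arsenic,0,0
GW24,residential,wet,selenium,17.0,1.0
GW24,residential,wet,antimony,0,0
GW24,residential,dry,arsenic,0,0
GW24,residential,dry,selenium,42.3,1.5
GW24,residential,dry,antimony,58.0,4.6
GW25,commercial,wet,arsenic,0,0
GW25,commercial,wet,selenium,26.7,8.9
GW25,commercial,wet,antimony,0,0
GW25,commercial,dry,arsenic,67.6,4.7
GW25,commercial,dry,selenium,36.0,4.4
GW25,commercial,dry,antimony,56.7,4.7
GW26,commercial,wet,arsenic,0,0
GW26,commercial,wet,selenium,35.3,2.1
GW26,commercial,wet,antimony,0,0
GW26,commercial,dry,arsenic,50.7,7.1
GW26,commercial,dry,selenium,53.7,5.9
GW26,commercial,dry,antimony,57.0,6.1
GW27,commercial,wet,arsenic,0,0
GW27,commercial,wet,selenium,9.0,2.0
GW27,commercial,wet,antimony,0,0
GW27,commercial,dry,arsenic,0,0
GW27,commercial,dry,selenium,40.0,7.9
GW27,commercial,dry,antimony,36.3,8.6
GW28,commercial,wet,arsenic,0,0
GW28,commercial,wet,selenium,7.67,3.1
GW28,commercial,wet,antimony,0,0
GW28,commercial,dry,arsenic,0,0
GW28,commercial,dry,selenium,43.7,9.5
GW28,commercial,dry,antimony,52.7,7.4
GW29,commercial,wet,arsenic,0,0
GW29,commercial,wet,selenium,12.3,4.5
GW29,commercial,wet,antimony,0,0
GW29,commercial,dry,arsenic,0,0
GW29,commercial,dry,selenium,42.3,10.3
GW29,commercial,dry,antimony,35.7,6.4
GW30,industrial,wet,arsenic,0,0
GW30,industrial,wet,selenium,1.33,2.3
GW30,industrial,wet,antimony,0,0
GW30,industrial,dry,arsenic,0,0
GW30,industrial,dry,selenium,17.7,5.0
GW30,industrial,dry,antimony,52.7,1.2
GW31,industrial,wet,arsenic,0,0
GW31,industrial,wet,selenium,5.67,4.0
GW31,industrial,wet,antimony,0,0
GW31,industrial,dry,arsenic,0,0
GW31,industrial,dry,selenium,27.3,4.9
GW31,industrial,dry,antimony,53.6,3.2
GW32,industrial,wet,arsenic,0,0
GW32,industrial,wet,selenium,6.33,5.7
GW32,industrial,wet,antimony,0,0
GW32,industrial,dry,arsenic,13.3,6.8
GW32,industrial,dry,selenium,26.0,0
GW32,industrial,dry,antimony,60.6,4.9
GW33,industrial,wet,arsenic,0,0
GW33,industrial,wet,selenium,3.67,6.4
GW33,industrial,wet,antimony,0,0
GW33,industrial,dry,arsenic,0,0
GW33,industrial,dry,selenium,18.7,6.7
GW33,industrial,dry,antimony,48.3,3.2
GW34,agricultural,wet,arsenic,0,0
GW34,agricultural,wet,selenium,23.67,6.7
GW34,agricultural,wet,antimony,0,0
GW34,agricultural,dry,arsenic,0,0
GW34,agricultural,dry,selenium,22.7,4.9
GW34,agricultural,dry,antimony,46.7,3.8
GW35,agricultural,wet,arsenic,0,0
GW35,agricultural,wet,selenium,18.0,4.4
GW35,agricultural,wet,antimony,0,0
GW35,agricultural,dry,arsenic,0,0
GW35,agricultural,dry,selenium,19.0,7.2
GW35,agricultural,dry,antimony,61.6,5.1
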