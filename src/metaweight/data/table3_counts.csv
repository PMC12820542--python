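outcome,predictor,significant,nonsignificant,total
attitude,effort expectancy,19,4,23
attitude,barriers,4,2,6
attitude,benefits,3,0,3
attitude,facilitating conditions,4,0,4
attitude,performance expectancy,20,2,22
attitude,privacy and security,2,1,3
attitude,social influence,6,1,7
behavioral intention,aesthetic appeal,4,0,4
behavioral intention,attitude,27,1,28
behavioral intention,barriers,7,6,13
behavioral intention,benefits,6,0,6
behavioral intention,compatibility,4,3,7
behavioral intention,effort expectancy,36,23,59
behavioral intention,ethics,2,1,3
behavioral intention,facilitating conditions,20,8,28
behavioral intention,financial cost,12,9,21
behavioral intention,functional congruence,4,1,5
behavioral intention,habit,7,0,7
behavioral intention,health,3,1,4
behavioral intention,health consciousness,7,4,11
behavioral intention,hedonic motivation,10,5,15
behavioral intention,image,4,2,6
behavioral intention,innovativeness,5,3,8
behavioral intention,perceived severity,2,3,5
behavioral intention,perceived vulnerability,3,5,8
behavioral intention,performance expectancy,68,10,78
behavioral intention,privacy and security,13,13,26
behavioral intention,reliability,5,0,5
behavioral intention,self-efficacy,10,1,11
behavioral intention,social influence,31,10,41
behavioral intention,technology anxiety,2,4,6
behavioral intention,trust,9,3,12
actual behavior,behavioral intention,16,1,17
actual behavior,effort expectancy,2,1,3
actual behavior,facilitating conditions,3,0,3
actual behavior,health consciousness,2,2,4
actual behavior,innovativeness,2,1,3
actual behavior,perceived vulnerability,2,1,3
actual behavior,performance expectancy,3,1,4
actual behavior,social influence,3,0,3
performance expectancy,barriers,2,3,5
performance expectancy,compatibility,6,2,8
performance expectancy,convenience,3,0,3
performance expectancy,effort expectancy,27,4,31
performance expectancy,facilitating conditions,2,2,4
performance expectancy,health consciousness,6,2,8
performance expectancy,image,3,4,7
performance expectancy,innovativeness,4,0,4
performance expectancy,privacy and security,4,2,6
performance expectancy,reliability,8,3,11
performance expectancy,self-efficacy,7,0,7
performance expectancy,social influence,8,3,11
performance expectancy,trialability,2,1,3
performance expectancy,trust,3,2,5
performance expectancy,task-technology fit,5,0,5
effort expectancy,compatibility,7,0,7
effort expectancy,facilitating conditions,6,0,6
effort expectancy,image,2,2,4
effort expectancy,innovativeness,7,0,7
effort expectancy,privacy and security,2,2,4
effort expectancy,reliability,4,0,4
effort expectancy,self-efficacy,7,0,7
effort expectancy,social influence,3,1,4
effort expectancy,trialability,2,1,3
effort expectancy,task-technology fit,3,0,3
task-technology fit,task characteristics,3,1,4
task-technology fit,technology characteristics,4,0,4
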