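criterion,weight_pct,subcriterion,within_weight_pct,recorded_overall_weight_pct
Benefit,22.8,Evidence base,26,5.9
Benefit,22.8,Size of problem,15.4,3.5
Benefit,22.8,Volume service treats,14.9,3.4
Benefit,22.8,Quality of life improvement,19.9,4.5
Benefit,22.8,Longevity of benefit,14,3.2
Benefit,22.8,Societal benefit (WTP survey),9.9,2.3
Cost-benefit,12.8,Total cost less societal benefit,100,12.8
Preventative,13.9,Prevention level,54,7.5
Preventative,13.9,Evidence base,46,6.4
Inequalities,11.8,Effect on vertical inequality,45.8,5.4
Inequalities,11.8,Effect on horizontal inequality,54.2,6.4
Safe/acceptable,9.1,Risk of untoward complication,26.8,2.4
Safe/acceptable,9.1,Longevity of side effects,27.6,2.5
Safe/acceptable,9.1,Pain associated with procedure,19.2,1.8
Safe/acceptable,9.1,Acceptable to patients,26.3,2.4
Cost,8.2,Units of dental activity generated per minute,18.4,1.5
Cost,8.2,Cost per quality of life improvement,47.4,3.9
Cost,8.2,Total cost,34.2,2.8
Workforce,7.2,Need to retrain workforce,55,4
Workforce,7.2,Uses dental care professionals,45,3.2
Patient responsibility,5.8,Onus on patient to care for oral health,100,5.8
Innovation,2.9,Current usage,100,2.9
Politically acceptable,2.8,MPs would find acceptable,100,2.8
Aesthetics,2.7,Intended to affect aesthetics,40,1.1
Aesthetics,2.7,Evidence base for aesthetic effect,60,1.6
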