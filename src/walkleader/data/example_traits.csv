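individual_id,breed,sex,age_years,weight_kg,dpq_fearfulness,dpq_aggression_people,dpq_activity_excitability,dpq_responsiveness_training,dpq_aggression_animals,dominance_points
V1,Vizsla,female,6.5,28,2.00,2.17,4.67,5.83,5.33,10
V2,Vizsla,female,7,26,1.08,2.83,5.00,6.83,5.33,14
V3,Vizsla,male,1.5,26,2.67,2.17,5.00,5.50,4.33,10
V4,Vizsla,female,1,26,1.25,1.50,5.17,5.50,3.44,2
V5,Vizsla,female,4,25,4.08,2.00,5.17,5.50,5.22,8
M,Mix,female,4,10,3.42,1.33,4.67,2.17,4.11,1
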