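component_id,Benefit,Cost-benefit,Preventative,Inequalities,Safe/acceptable,Cost,Workforce,Patient responsibility,Innovation,Politically acceptable,Aesthetics,recorded_final_score
out_of_hours_pain,0.73,2.00,0.00,1.54,0.94,1.29,0.65,0.00,-2.00,1.00,0.00,0.81
helpline_link,0.42,1.00,0.00,1.54,2.00,-0.26,2.00,0.00,-0.50,1.00,0.00,0.72
dph_input,0.68,-1.00,1.31,1.54,2.00,-0.26,-1.00,1.50,-1.00,1.00,0.00,0.57
care_homes,-0.57,2.00,0.46,1.31,1.54,0.82,0.00,0.00,-1.00,1.00,0.40,0.56
preventive_sessions,0.89,-2.00,1.54,-0.77,2.00,-0.10,0.35,2.00,-1.00,2.00,1.00,0.44
new_practices,-0.15,1.00,0.46,-0.46,2.00,-0.61,-1.00,1.00,-2.00,2.00,0.40,0.23
moderate_severe_orthodontics,0.32,1.00,0.00,0.00,-0.37,-0.82,0.65,0.00,-2.00,1.00,1.40,0.16
cbt,0.61,-2.00,0.00,-0.27,1.90,-1.16,1.45,1.00,-1.00,1.00,0.00,0.09
orthognathic_surgery,-0.66,2.00,0.00,0.27,-1.21,-0.61,0.65,0.00,-2.00,1.00,1.40,0.03
homeless_care,-0.66,-2.00,0.46,1.73,1.07,-0.82,0.10,0.50,-1.00,2.00,1.00,-0.02
routine_scaling,0.50,-1.00,-0.73,0.04,1.54,-1.66,1.55,0.00,-2.00,0.00,0.40,-0.04
molar_endodontics,0.18,1.00,-0.92,-0.54,0.20,-1.29,0.65,0.00,-2.00,1.00,0.00,-0.09
adult_orthodontics,-0.01,-1.00,0.00,-0.77,-0.37,0.21,0.65,0.00,-2.00,1.00,1.40,-0.18
moderate_orthodontics,0.09,-1.00,0.00,-0.77,-0.63,-0.13,0.65,0.00,-2.00,1.00,1.40,-0.21
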