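component_id,name,kind,cost_gbp_m,currently_provided,final_score,votes_for_funding,recorded_decision
moderate_orthodontics,Moderate-need orthodontics (IOTN 3),disinvestment,44,True,-0.21,3,Disinvest
adult_orthodontics,Adult orthodontics,disinvestment,11,True,-0.18,3,Disinvest
routine_scaling,Routine scale and polish,disinvestment,174,True,-0.04,2,Disinvest
molar_endodontics,Molar root canal treatment,disinvestment,190,True,-0.09,6,Continue
orthognathic_surgery,Orthognathic surgery,disinvestment,20,True,0.03,7,Continue
moderate_severe_orthodontics,Moderate- and severe-need orthodontics,disinvestment,99,True,0.16,7,Continue
out_of_hours_pain,Out-of-hours dental pain service,disinvestment,54,True,0.81,7,Continue
homeless_care,Dental care for the homeless,investment,190,False,-0.02,5,No investment
cbt,Cognitive behavioural therapy for dental anxiety,investment,824,False,0.09,0,No investment
preventive_sessions,Preventative advice sessions in practice,investment,659,False,0.44,0,No investment
new_practices,New dental practice places in oversubscribed areas,investment,135,False,0.23,7,Invest
care_homes,Expanded dental services in care homes,investment,13,False,0.56,8,Invest
dph_input,Dental public health input into local authority contracts,investment,5,False,0.57,7,Invest
helpline_link,Direct booking link from the national NHS helpline,investment,2,False,0.72,6,Invest
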