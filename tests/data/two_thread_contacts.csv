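patient_id,contact_id,date,provider_id,provider_level,specialty,reasons
pt1,O1,2020-01-06,ortho1,AMBULATORY_SPECIALIST,orthopedics,knee pain
pt1,G1,2020-01-11,gp1,GP,,blood pressure
pt1,O2,2020-02-05,ortho1,AMBULATORY_SPECIALIST,orthopedics,knee follow-up
pt1,P1,2020-02-15,physio1,ALLIED_HEALTH,physiotherapy,
pt1,G2,2020-03-06,gp1,GP,,monitoring;blood pressure
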