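patient_id,src_contact_id,dst_contact_id,edge_type
pt1,O1,O2,FOLLOWUP
pt1,O2,P1,REFERRAL
pt1,G1,G2,FOLLOWUP
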