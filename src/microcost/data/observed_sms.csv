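category,phase,resource_class,level,arm,amount,currency,note
hardware,start_up,capital,intervention,sms,61.48,USD,
software,start_up,capital,intervention,sms,4042.27,USD,
training,start_up,capital,intervention,sms,61.20,USD,
office_equipment,start_up,capital,intervention,sms,422.71,USD,one-cent reconciliation with subtotal and arm total
staff_salaries,implementation,recurring,intervention,sms,1849.48,USD,
connectivity,implementation,recurring,intervention,sms,3676.02,USD,
office_consumables,implementation,recurring,intervention,sms,20.74,USD,one-cent reconciliation with subtotal and arm total
counselor_time,implementation,recurring,counselor,sms,1538.21,USD,
office_equipment,implementation,recurring,counselor,sms,65.10,USD,
office_consumables,implementation,recurring,counselor,sms,18.30,USD,
printed_material,implementation,recurring,participant,sms,459.60,USD,
phone_credit_counselor,implementation,recurring,participant,sms,3.26,USD,one-cent reconciliation with subtotal and arm total
phone_credit_participant,implementation,recurring,participant,sms,293.33,USD,
sms_charges,implementation,recurring,participant,sms,0.00,USD,
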