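category,phase,resource_class,level,arm,amount,currency,note
hardware,start_up,capital,intervention,ivr,102.47,USD,
software,start_up,capital,intervention,ivr,7139.25,USD,
training,start_up,capital,intervention,ivr,93.60,USD,
office_equipment,start_up,capital,intervention,ivr,645.33,USD,
staff_salaries,implementation,recurring,intervention,ivr,2828.62,USD,
connectivity,implementation,recurring,intervention,ivr,5029.41,USD,
office_consumables,implementation,recurring,intervention,ivr,31.73,USD,
counselor_time,implementation,recurring,counselor,ivr,2535.98,USD,
office_equipment,implementation,recurring,counselor,ivr,99.56,USD,
office_consumables,implementation,recurring,counselor,ivr,30.50,USD,one-cent reconciliation with arm total
printed_material,implementation,recurring,participant,ivr,700.89,USD,
phone_credit_counselor,implementation,recurring,participant,ivr,4.96,USD,
phone_credit_participant,implementation,recurring,participant,ivr,0.00,USD,
sms_charges,implementation,recurring,participant,ivr,0.00,USD,
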