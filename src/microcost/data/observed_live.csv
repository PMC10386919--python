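category,phase,resource_class,level,arm,amount,currency,note
hardware,start_up,capital,intervention,live,0.00,USD,
software,start_up,capital,intervention,live,774.14,USD,
training,start_up,capital,intervention,live,245.20,USD,
office_equipment,start_up,capital,intervention,live,744.04,USD,
staff_salaries,implementation,recurring,intervention,live,7410.00,USD,one-cent reconciliation with subtotal and arm total
connectivity,implementation,recurring,intervention,live,398.70,USD,
office_consumables,implementation,recurring,intervention,live,1980.00,USD,
counselor_time,implementation,recurring,counselor,live,9179.40,USD,
office_equipment,implementation,recurring,counselor,live,260.81,USD,
office_consumables,implementation,recurring,counselor,live,83.12,USD,
printed_material,implementation,recurring,participant,live,1838.40,USD,
phone_credit_counselor,implementation,recurring,participant,live,169.11,USD,
phone_credit_participant,implementation,recurring,participant,live,0.00,USD,
sms_charges,implementation,recurring,participant,live,0.00,USD,
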