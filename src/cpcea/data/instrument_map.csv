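item_id,domain,orientation
q01,functioning,higher_is_better
q02,functioning,higher_is_better
q03,functioning,higher_is_better
q04,functioning,higher_is_better
q05,functioning,higher_is_better
q06,functioning,higher_is_better
q07,functioning,higher_is_better
q08,functioning,higher_is_better
q09,functioning,higher_is_better
q10,functioning,higher_is_better
q11,functioning,higher_is_better
q12,participation_physical,higher_is_better
q13,participation_physical,higher_is_better
q14,participation_physical,higher_is_better
q15,participation_physical,higher_is_better
q16,participation_physical,higher_is_better
q17,participation_physical,higher_is_better
q18,participation_physical,higher_is_better
q19,participation_physical,higher_is_better
q20,participation_physical,higher_is_better
q21,participation_physical,higher_is_better
q22,participation_physical,higher_is_better
q23,participation_physical,higher_is_better
q24,access_services,higher_is_better
q25,access_services,higher_is_better
q26,access_services,higher_is_better
q27,access_services,higher_is_better
q28,access_services,higher_is_better
q29,access_services,higher_is_better
q30,access_services,higher_is_better
q31,access_services,higher_is_better
q32,access_services,higher_is_better
q33,emotional_wellbeing,higher_is_better
q34,emotional_wellbeing,higher_is_better
q35,emotional_wellbeing,higher_is_better
q36,emotional_wellbeing,higher_is_better
q37,emotional_wellbeing,higher_is_better
q38,emotional_wellbeing,higher_is_better
q39,emotional_wellbeing,higher_is_better
q40,emotional_wellbeing,higher_is_better
q41,family_health,higher_is_better
q42,family_health,higher_is_better
q43,family_health,higher_is_better
q44,family_health,higher_is_better
q45,family_health,higher_is_better
q46,family_health,higher_is_better
q47,family_health,higher_is_better
q48,family_health,higher_is_better
q49,family_health,higher_is_better
q50,pain_disability,lower_is_better
q51,pain_disability,lower_is_better
q52,pain_disability,lower_is_better
q53,pain_disability,lower_is_better
q54,pain_disability,lower_is_better
q55,pain_disability,lower_is_better
q56,pain_disability,lower_is_better
q57,pain_disability,lower_is_better
q58,social_wellbeing,higher_is_better
q59,social_wellbeing,higher_is_better
q60,social_wellbeing,higher_is_better
q61,social_wellbeing,higher_is_better
q62,social_wellbeing,higher_is_better
q63,social_wellbeing,higher_is_better
q64,social_wellbeing,higher_is_better
q65,social_wellbeing,higher_is_better
q66,social_wellbeing,higher_is_better
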