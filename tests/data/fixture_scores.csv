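subject_id,timepoint,mb1_individual,mb2_individual,p_stay_common_rew,p_stay_common_unrew,p_stay_rare_rew,p_stay_rare_unrew,n_common_rew,n_common_unrew,n_rare_rew,n_rare_unrew
agent000,baseline,0.5075757575757575,0.0578342849215977,0.7727272727272727,0.4166666666666667,0.18181818181818182,0.3333333333333333,22,12,11,3
agent001,baseline,0.25349650349650343,-0.0020433099535966948,0.75,0.7692307692307693,0.7272727272727273,1.0,20,13,11,4
agent002,baseline,0.1791979949874687,0.1374664169728752,0.631578947368421,0.5,0.6666666666666666,0.7142857142857143,19,16,6,7
agent003,baseline,-0.3260233918128655,-0.16868208327985545,0.3684210526315789,0.5,0.4444444444444444,0.25,19,12,9,8
agent004,baseline,0.27083333333333326,0.36490668047860075,0.6666666666666666,0.4375,0.625,0.6666666666666666,18,16,8,6
agent005,baseline,-0.4274509803921569,-0.3293027277521867,0.7058823529411765,0.8,0.8333333333333334,0.5,17,15,12,4
agent000,followup,-0.26344537815126057,-0.22633323586686083,0.5294117647058824,0.65,1.0,0.8571428571428571,17,20,4,7
agent001,followup,0.7673202614379084,0.2638199006374744,0.7647058823529411,0.35294117647058826,0.4444444444444444,0.8,17,17,9,5
agent002,followup,0.2286843591191418,0.17574379232231796,0.8260869565217391,0.45454545454545453,0.8571428571428571,0.7142857142857143,23,11,7,7
agent003,followup,0.07792207792207795,-0.11757215631789752,0.7142857142857143,0.7333333333333333,0.6363636363636364,0.7333333333333333,7,15,11,15
agent004,followup,0.2654761904761904,0.16382215082348672,0.7,0.6428571428571429,0.625,0.8333333333333334,20,14,8,6
agent005,followup,0.32979242979242984,0.10905927320918973,0.6111111111111112,0.5384615384615384,0.6,0.8571428571428571,18,13,10,7
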