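{"shared": {"p_T_dup": 0.3148536742328091, "p_T_death": 1.1620434635172197, "p_Treg_kills_Teff": 0.010005393935118397, "p_NK_kills_Teff": 0.01001511845143942, "p_IFNg_prod": 1.2830479421984866, "p_IL17_prod": 0.28063852651961274, "p_IL10_prod": 11.434259708823229, "p_IFNg_prod_in": 3.746325760757328, "p_IL17_prod_in": 0.3239366522771851, "p_IFNg_cons": 0.2533799355662471, "p_IL17_cons": 0.09631258177759322, "p_IL10_cons": 7.73015609681493, "p_BBB_damage": 4.730172896850899, "p_BBB_repair": 0.019728219603363337, "p_pass": 0.09716921775837485, "p_Teff_kills_ODC": 0.0010018247099832548, "p_remyelination": 0.09998257971319087, "p_memory_reactivation": 0.052618732256489935}, "activation": {"HD": {"p_Teff_Activation": 0.042998196702875524, "p_Treg_Activation": 1.4511138578766967}, "MS": {"p_Teff_Activation": 0.5738205403479585, "p_Treg_Activation": 0.1999357602622903}}, "loss": 0.0008158347611639777, "loss_per_group": {"HD": 0.000799677955301002, "MS": 1.6156805862975752e-05}, "n_starts": 8, "seed": 1, "trace": [0.003452758580992358, 0.003479646126553659, 0.003447302403940242, 0.00344704339638058, 0.00348937866212141, 0.0034464999438475756, 0.005476682267539451, 0.003452213794602628]}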