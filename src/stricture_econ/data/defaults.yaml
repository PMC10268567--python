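# Default model inputs: recurrent anterior male urethral stricture,
# NHS England perspective, 2019/20 GBP. Monthly cycles, 5-year horizon.
#
# Transition inputs
monthly_p_recur_endo: 0.163            # ROBUST III, from 88.1% 12-month recurrence
monthly_p_recur_optilume: 0.026        # ROBUST III, from 26.9% 12-month recurrence
monthly_p_recur_urethroplasty: 0.009   # OPEN RCT, from 24-month recurrence
p_treated_after_recurrence: 0.90
split_urethroplasty_after_endo_or_optilume: 0.70
split_repeat_endo_or_optilume: 0.30
split_repeat_urethroplasty_after_urethroplasty: 0.12
split_endo_or_optilume_after_urethroplasty: 0.88
median_days_to_treatment_endo_optilume: 47.5
median_days_to_treatment_urethroplasty: 90
monthly_p_death: 0.0

# Costs (GBP)
cost_endo_procedure: 1196.0            # NHS reference cost LB55A, weighted average
cost_urethroplasty_procedure: 4761.0   # NHS reference cost LB29A
cost_optilume_incl_device: 1986.0
cost_optilume_excl_device: 635.0
cost_optilume_device: 1350.0
cost_predilation: 20.36
ae_cost_optilume: 15.16
ae_cost_endo: 63.40
ae_cost_urethroplasty: 17.46
training_per_patient_optilume: 8.53
monthly_cost_cured: 18.33              # two urology outpatient visits per year
monthly_cost_recurrence: 44.74         # four urology outpatient visits per year

# Engine settings
horizon_cycles: 60
cycle_length_months: 1.0
annual_discount_rate_costs: 0.035
starting_age: 59
days_per_month: 30.4375                # 365.25 / 12
recurrence_exit_mode: geometric        # geometric | fixed_tunnel
include_predilation: false
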