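marker	statistic	value
acidity	intercept	0.39
acidity	sd_error	0.04
acidity	mae	0.03
acidity	r	0.96
acidity	loo_residual_variance_pct	10.79
acidity	loo_residual_sd	0.05
acidity	loo_explained_variance_pct	89.21
acidity	loo_mean_prediction_error	0.04
k232	intercept	2.55
k232	sd_error	0.19
k232	mae	0.14
k232	r	0.97
k232	loo_residual_variance_pct	7.83
k232	loo_residual_sd	0.21
k232	loo_explained_variance_pct	92.17
k232	loo_mean_prediction_error	0.17
k270	intercept	0.74
k270	sd_error	0.13
k270	mae	0.09
k270	r	0.98
k270	loo_residual_variance_pct	6.48
k270	loo_residual_sd	0.15
k270	loo_explained_variance_pct	93.52
k270	loo_mean_prediction_error	0.11
delta_k	intercept	0.06951
delta_k	sd_error	0.02
delta_k	mae	0.01
delta_k	r	0.97
delta_k	loo_residual_variance_pct	7.44
delta_k	loo_residual_sd	0.02
delta_k	loo_explained_variance_pct	92.56
delta_k	loo_mean_prediction_error	0.02
pv	intercept	13.05556
pv	sd_error	1.73
pv	mae	1.22
pv	r	0.94
pv	loo_residual_variance_pct	18.33
pv	loo_residual_sd	1.97
pv	loo_explained_variance_pct	81.67
pv	loo_mean_prediction_error	1.57
anv	intercept	18.47035
anv	sd_error	5.25
anv	mae	3.34
anv	r	0.96
anv	loo_residual_variance_pct	13.48
anv	loo_residual_sd	6.17
anv	loo_explained_variance_pct	86.52
anv	loo_mean_prediction_error	4.35
totox	intercept	44.56894
totox	sd_error	10.72
totox	mae	7.37
totox	r	0.9
totox	loo_residual_variance_pct	27.36
totox	loo_residual_sd	11.99
totox	loo_explained_variance_pct	72.64
totox	loo_mean_prediction_error	8.88
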