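# Published multivariable proportional-odds model for the UEF categorical
# index (cross-sectional development cohort, n = 352; Fried stage outcome).
# Orientation: P(Y <= k | x) = logistic(alpha_k + x' beta), categories ordered
# non-frail < pre-frail < frail; the moment enters as its natural logarithm;
# sex coded as an indicator for female.
version: 1
n_obs: 352
intercepts:
  alpha_nonfrail: -2.6304
  alpha_prefrail: 1.5140
coefficients:
  speed: 0.0025            # deg/s
  flexibility: 0.0207      # deg
  log_moment: 0.7176       # ln(Nm)
  speed_variability: -0.0441  # %
  speed_reduction: -0.0342    # % (negative = slowing)
  flexion_number: 0.0647   # count / 20 s
  sex_female: 0.1214       # indicator
  age: -0.0206             # years
  bmi: -0.0611             # kg/m^2
standard_errors:
  alpha_nonfrail: 2.0702
  alpha_prefrail: 2.0759
  speed: 0.0010
  flexibility: 0.0069
  log_moment: 0.3278
  speed_variability: 0.0206
  speed_reduction: 0.0153
  flexion_number: 0.0284
  sex_female: 0.1570
  age: 0.0158
  bmi: 0.0284
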