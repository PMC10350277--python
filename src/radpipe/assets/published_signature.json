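{
 "name": "OCSCC-T2w-waveletLLL-5feature-OS",
 "description": "Published 5-feature MRI radiomic prognostic signature for overall survival in locally advanced oral cavity squamous cell carcinoma. Mean/SD are the training-cohort statistics used for Z-score normalization; coef are the Cox regression coefficients on the Z-scored scale. The training-median risk threshold was not reported and is null: stratification requires a user-supplied threshold or calibration cohort.",
 "features": [
  "T_T2_waveletLLL_glrlm_LongRunEmphasis",
  "T_T2_waveletLLL_glrlm_RunVariance",
  "T_T2_waveletLLL_glrlm_RunPercentage",
  "T_T2_waveletLLL_firstorder_Range",
  "T_T2_waveletLLL_glrlm_ShortRunEmphasis"
 ],
 "mean": [1.27, 0.10, 0.93, 7.49, 0.94],
 "sd": [0.21, 0.08, 0.04, 3.85, 0.03],
 "coef": [73.07, -59.29, -43.98, 0.34, 58.07],
 "threshold": null
}
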