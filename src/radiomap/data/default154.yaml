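# Default radiomics feature panel: 17 intensity + 137 texture features.
#
# Texture families and parameterization:
#   glcm   : grey-level co-occurrence, distance 1, 13 unique 3D directions;
#            "merged" sums direction matrices before feature computation,
#            "averaged" computes features per direction and averages them.
#   glrlm  : grey-level run-length, 13 directions, merged / averaged as above.
#   glszm  : grey-level size-zone, zones by 26-connectivity.
#   ngtdm  : neighbourhood grey-tone difference, 26-neighbourhood.
#   ngldm  : neighbourhood grey-level dependence, 26-neighbourhood, distance 1,
#            included at two coarseness settings (alpha = 0 and alpha = 1).
name: default154
blocks:
  - family: intensity
    prefix: intensity
    features:
      - mean
      - variance
      - skewness
      - kurtosis
      - median
      - minimum
      - percentile_10
      - percentile_90
      - maximum
      - interquartile_range
      - range
      - mean_absolute_deviation
      - robust_mean_absolute_deviation
      - median_absolute_deviation
      - coefficient_of_variation
      - energy
      - root_mean_square
  - family: glcm
    aggregation: merged
    prefix: glcm
    features: &glcm_features
      - joint_maximum
      - joint_average
      - joint_variance
      - joint_entropy
      - difference_average
      - difference_variance
      - difference_entropy
      - sum_average
      - sum_variance
      - sum_entropy
      - angular_second_moment
      - contrast
      - dissimilarity
      - inverse_difference
      - inverse_difference_normalized
      - inverse_difference_moment
      - inverse_difference_moment_normalized
      - inverse_variance
      - correlation
      - autocorrelation
      - cluster_tendency
      - cluster_shade
      - cluster_prominence
      - information_correlation_1
      - information_correlation_2
  - family: glcm
    aggregation: averaged
    prefix: glcm_avg
    features: *glcm_features
  - family: glrlm
    aggregation: merged
    prefix: glrlm
    features: &glrlm_features
      - short_run_emphasis
      - long_run_emphasis
      - low_grey_level_run_emphasis
      - high_grey_level_run_emphasis
      - short_run_low_grey_level_emphasis
      - short_run_high_grey_level_emphasis
      - long_run_low_grey_level_emphasis
      - long_run_high_grey_level_emphasis
      - grey_level_nonuniformity
      - grey_level_nonuniformity_norm
      - run_length_nonuniformity
      - run_length_nonuniformity_norm
      - run_percentage
      - grey_level_variance
      - run_length_variance
      - run_entropy
  - family: glrlm
    aggregation: averaged
    prefix: glrlm_avg
    features: *glrlm_features
  - family: glszm
    prefix: glszm
    features:
      - small_zone_emphasis
      - large_zone_emphasis
      - low_grey_level_zone_emphasis
      - high_grey_level_zone_emphasis
      - small_zone_low_grey_level_emphasis
      - small_zone_high_grey_level_emphasis
      - large_zone_low_grey_level_emphasis
      - large_zone_high_grey_level_emphasis
      - grey_level_nonuniformity
      - grey_level_nonuniformity_norm
      - zone_size_nonuniformity
      - zone_size_nonuniformity_norm
      - zone_percentage
      - grey_level_variance
      - zone_size_variance
      - zone_size_entropy
  - family: ngtdm
    prefix: ngtdm
    features:
      - coarseness
      - contrast
      - busyness
      - complexity
      - strength
  - family: ngldm
    alpha: 0
    prefix: ngldm
    features: &ngldm_features
      - low_dependence_emphasis
      - high_dependence_emphasis
      - low_grey_level_count_emphasis
      - high_grey_level_count_emphasis
      - low_dependence_low_grey_level_emphasis
      - low_dependence_high_grey_level_emphasis
      - high_dependence_low_grey_level_emphasis
      - high_dependence_high_grey_level_emphasis
      - grey_level_nonuniformity
      - grey_level_nonuniformity_norm
      - dependence_count_nonuniformity
      - dependence_count_nonuniformity_norm
      - dependence_count_percentage
      - grey_level_variance
      - dependence_count_variance
      - dependence_count_entropy
      - dependence_count_energy
  - family: ngldm
    alpha: 1
    prefix: ngldm_a1
    features: *ngldm_features
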