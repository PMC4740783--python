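"""Temporal response correlations: simultaneous vs trial-shuffled.

Simulates a shank with shared (common-input) noise c = 0.5, computes the
pairwise max-lag response correlations (|tau| <= 10 ms) for simultaneously
recorded trials and for trial-shuffled surrogates, then asks whether
simultaneity changes pooled decoding accuracy when the shared noise carries
no stimulus information.
"""

import logging

from vocdisc import CrossValPlan, SegmentSpec, StimulusSet, \
    classify_with_corr_features, generate_population, \
    generate_vocalization_set, pairwise_corr_matrix, shuffle_trials, \
    simulate_responses

logging.getLogger("vocdisc").setLevel(logging.ERROR)  # hide sparse-trace notes

calls = generate_vocalization_set(seed=1)
one_call = StimulusSet(calls.stimuli[:1], calls.trial_length)
population = generate_population("linear_double_shank", 6, (0.5, 12.0),
                                 seed=3, shared_noise_c=0.5)
recording = simulate_responses(population, one_call, n_trials=10, seed=5)
surrogate, _ = shuffle_trials(recording, seed=9)

sim = pairwise_corr_matrix(recording, one_call.ids[0])
shuf = pairwise_corr_matrix(surrogate, one_call.ids[0])
sim0 = pairwise_corr_matrix(recording, one_call.ids[0], tau_max_ms=0.0)
shuf0 = pairwise_corr_matrix(surrogate, one_call.ids[0], tau_max_ms=0.0)
print(f"mean pairwise CorrRes, |tau| <= 10 ms : "
      f"simultaneous {sim.mean_pair_value():.3f}   "
      f"shuffled {shuf.mean_pair_value():.3f}")
print(f"mean pairwise CorrRes, tau = 0        : "
      f"simultaneous {sim0.mean_pair_value():.3f}   "
      f"shuffled {shuf0.mean_pair_value():.3f}")

# Decoding with correlation-augmented features, all 11 calls:
full = generate_vocalization_set(seed=1)
pop5 = generate_population("linear_double_shank", 5, (0.5, 12.0), seed=3,
                           shared_noise_c=0.5)
rec5 = simulate_responses(pop5, full, n_trials=20, seed=5)
shuf5, _ = shuffle_trials(rec5, seed=9)
seg = SegmentSpec(0.12, 0.1)
plan = CrossValPlan(seed=11)
cc_sim = classify_with_corr_features(rec5, pop5.unit_ids, seg, plan).cc
cc_shuf = classify_with_corr_features(shuf5, pop5.unit_ids, seg, plan).cc
print(f"pooled CC with CorrRes features       : "
      f"simultaneous {cc_sim:.1f}%   shuffled {cc_shuf:.1f}%")

# Shared noise makes simultaneous trials visibly more correlated than
# shuffled ones (strongly so at zero lag), yet because that co-fluctuation
# is the same for every call it contributes no class information: the
# pooled decoding accuracy is essentially unchanged by shuffling.
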