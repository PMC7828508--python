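# oaad — online auditory attention detection from EEG

`oaad` implements an online auditory attention detection (AAD) pipeline for
dichotic listening: from multichannel EEG it tracks, once per second, which
of two simultaneously presented speech streams a listener is attending. It
is aimed at researchers prototyping neuro-steered hearing devices or
attention-decoding experiments who need a transparent, fully testable
reference implementation that runs on streamed data.

## The model

Cortical activity in the 2–8 Hz band entrains to the slow amplitude
envelope of attended speech more strongly than to ignored speech. A
backward (stimulus-reconstruction) decoder `D(τ, n)` maps EEG channels `n`
at post-stimulus lags `τ ∈ [0, 250] ms` back to the envelope estimate

    Ŝ(t) = Σ_n Σ_τ D(τ, n) · R(t + τ, n)

with the ridge solution `D = (R Rᵀ + λI)⁻¹ R Sᵀ` (λ = 10 on z-scored
data). The *online* model slides a `W`-second window with hop `M` over
each `T = 60 s` construction trial, fits one ridge decoder per snippet
against the attended envelope, and averages all `I · J` snippet decoders
(`J = ⌊(T − W)/M⌋ + 1`). At test time the reconstruction from each new
window is Pearson-correlated with the left and right envelopes; the larger
(optionally causally smoothed) coefficient gives the attended direction at
time `(j − 1)·M + W`, i.e. one decision per second at the default
`W = 15 s, M = 1 s`. Direction-biased variants average only left- or only
right-attended trials and are evaluated matched-side. Accuracy is judged
against the exact binomial chance level (smallest k/n with
CDF ≥ 0.95).

A synthetic generator produces dichotic sessions from a known lagged
forward model (attended gain > ignored gain, plus noise), so construction,
streaming and detection are testable end-to-end without recordings.

## Worked example

```python
from oaad import ForwardModel, SessionPlan, generate_session, run_online_session
from oaad.detection import binomial_chance_level, evaluate_accuracy

plan = SessionPlan(n_construction=15, n_test_fixed=12, n_test_switching=4)
session = generate_session(plan, ForwardModel.default(rng=1), rng_seed=1)
result = run_online_session(plan, session.trials)     # streamed construction + test
df = result.records
single = df[(df.model == "single") & (df.k == 1)]
print(len(single))                                        # 736 detections (16 trials x 46)
print(round(evaluate_accuracy(single), 2))                # 76.63 (% correct)
print(round(binomial_chance_level(len(single), 0.5), 2))  # 52.99 (% chance level)
```

The session has 16 test trials of 60 s each, so the single model emits
46 decisions per trial = 736 in total; 76.63 % of them match the scheduled
attended side, well above the 52.99 % binomial chance level for n = 736.

A thin CLI wraps the same functions:

```bash
oaad simulate --seed 1 --out session_dir/
oaad run-session --session session_dir/ --out records.csv
oaad gridsearch --sessions session_dir/ --out results.csv
```

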