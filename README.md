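# painfusion

Objective pain-intensity assessment from multimodal physiological
sensing.  Self-reported pain ratings are subjective and often
uninformative exactly when they matter most (patients who cannot
communicate, acute care, individual differences in pain perception);
this package implements and evaluates an analysis pipeline that
estimates pain states from nine sensing modalities instead: facial
action-unit probabilities (FE), EEG, pupil diameter (EM), skin
conductance (SC), blood volume pulse (BVP), EMG, respiration (RR), skin
temperature (ST) and blood pressure (BP).

It is aimed at researchers in physiological computing and biomedical
signal processing who want a fully reproducible, end-to-end testbed for
cold-pressor-style pain experiments — including a synthetic cohort
generator, so every stage runs and is testable without access to any
recordings.

## What it computes

**Windows and labels.** Recordings are cut into 20-s windows: one
relaxed baseline per day, then one window per iced-water immersion
session, each with a 0–10 verbal rating (VRS).  Windows are classed as
baseline **B** (or VRS 0), low pain **LP** (VRS 1–5) or high pain **HP**
(VRS 6–10).

**Features.**  Per window: mean probabilities of 17 facial action
units; EEG log band power per channel in δ [1,3), θ [4,8), α [8,13),
β [13,30), γ [30,50) Hz after a zero-phase 1–50 Hz band-pass (Welch
estimate); pupil mean/SD after velocity-based blink interpolation; SC
and ST mean and slope; heart and respiration rates by peak detection;
EMG RMS; day-level post−pre cuff deltas for BP.

**Cascade classifier.**  A two-stage SVM tree: stage 1 separates
no-pain from pain, stage 2 low from high pain, with Platt-calibrated
probabilities.  Each modality's cascade yields a sensor score

s_i = p(pain)·(1 + p(HP|pain)) ∈ [0, 2],

the expected class code (B=0, LP=1, HP=2).

**Decision-level fusion.**  Sensor scores combine as fs = Σᵢ wᵢ·sᵢ with
nonnegative weights summing to one, learned by a real-coded genetic
algorithm (population 50, ≤50 generations, crossover 0.8, mutation
0.02) that minimizes threshold violations |fs − true| > 0.5 with mean
absolute error as tie-break.

**Evaluation.**  Stratified 5-fold and leave-one-subject-out (LOSO)
cross-validation with per-class F1; a modality-ablation comparison
(all sensors / EEG+FE only / all but EEG+FE); and a repeated-measures
ANOVA screen of each summary feature across the three pain states.

See `docs/methods.md` for the full model description and design
rationale.

## Worked example

```python
from painfusion import GeneratorConfig, simulate_features
from painfusion.evaluation import kfold_cv, loso_cv, significance_screen
from painfusion.fusion import run_modality_sets

df = simulate_features(GeneratorConfig(), seed=0)   # 26 subjects x 3 days
X = df.drop(columns=["subject", "day", "window", "vrs", "label"])

kf = kfold_cv(X, df["label"], k=5, seed=0)
lo = loso_cv(X, df["label"], df["subject"])
print(kf.macro_f1, lo.macro_f1)
```

prints `0.777 0.624`: within-subject validation (5-fold) clearly beats
cross-subject validation (LOSO) because pain physiology differs between
subjects — a classifier that has never seen a subject generalizes worse
to them.  Continuing with fusion and the significance screen
(`examples/05_evaluation_and_anova.py`):

```
fusion set all        macro-F1 0.663
fusion set eeg_fe     macro-F1 0.664
fusion set no_eeg_fe  macro-F1 0.291
```

removing EEG and facial expression — the two most informative
modalities — collapses fusion performance, while

```
            feature  variant          F            p
            sc.mean repeated  34.239166 4.298102e-10
      em.pupil_mean repeated  48.129323 2.219276e-12
            st.mean repeated  12.192208 4.866325e-05
       bp.sys_delta   paired  73.228088 6.735520e-09
eeg.region.Parietal repeated 961.012486 1.263106e-40
             bvp.hr repeated   3.944873 2.565719e-02
            emg.rms repeated   0.559523 5.750183e-01
            rr.rate repeated   0.965882 3.876352e-01
```

shows the expected physiology: skin conductance, pupil diameter, skin
temperature, systolic blood pressure and parietal EEG power
discriminate the three pain states strongly, while heart rate, EMG and
respiration carry no configured effect.

Each script in `examples/` demonstrates one capability (cohort
simulation, feature extraction, the cascade, GA fusion, evaluation) and
prints what the numbers mean.  A thin CLI covers the on-disk pipeline:

```sh
painfusion simulate --config cfg.yaml --out data/ --seed 1
painfusion featurize --data data/ --out features.csv
painfusion evaluate --features features.csv --scheme loso --out report.json
painfusion anova --features features.csv --out anova.csv
painfusion fuse --features features.csv --out fusion.json
```

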