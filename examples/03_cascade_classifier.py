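"""Train the two-stage cascade and read its probabilities and scores.

Stage 1 separates baseline from pain; stage 2 (consulted only when stage
1 says "pain") separates low from high pain.  The continuous sensor
score p(pain)*(1 + p(HP|pain)) is the expected class code in [0, 2].
"""

from painfusion import GeneratorConfig, simulate_features
from painfusion.cascade import (
    predict_label,
    predict_probabilities,
    predict_score,
    train_cascade,
)

df = simulate_features(GeneratorConfig(n_subjects=8, n_days=2, seed=1))
X = df.drop(columns=["subject", "day", "window", "vrs", "label"])
train = df["subject"] < "S07"

model = train_cascade(X[train], df.loc[train, "label"])
acc = (predict_label(model, X[~train]) == df.loc[~train, "label"]).mean()
print(f"held-out window accuracy: {acc:.2f} on {(~train).sum()} windows")

held = df[~train]
picks = held.groupby("label", sort=False).head(1).sort_values("label")
p_pain, p_hp = predict_probabilities(model, X.loc[picks.index])
scores = predict_score(model, X.loc[picks.index])
for i, (_, row) in enumerate(picks.iterrows()):
    print(f"true {row['label']:>2}: p(pain)={p_pain[i]:.2f}  "
          f"p(HP|pain)={p_hp[i]:.2f}  score={scores[i]:.2f}")
print("scores near 0/1/2 correspond to baseline/low/high pain")
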