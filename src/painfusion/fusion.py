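"""Decision-level fusion of per-modality sensor scores.

The fused score of a window is the weighted sum over the nine sensors,

    fs = sum_i w_i * s_i,        w_i >= 0,  sum_i w_i = 1,

where s_i in [0, 2] is sensor i's expected-class-code score and the
weights lie on the unit simplex (imposed for identifiability; the fused
score then stays on the class-code scale).  Weights are learned by a
real-coded genetic algorithm whose fitness counts threshold violations
— windows where |fused - true| exceeds a tolerance of half a class step —
with mean absolute error as the tie-break.  GA operators: tournament
selection, arithmetic-blend crossover, per-gene Gaussian mutation,
elitism, and projection back to the simplex after every operator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cascade import CascadeConfig, predict_score, train_per_modality
from .evaluation import EvaluationReport, f1_per_class  # noqa: F401 (re-export convenience)
from .modalities import CODE_LABELS, LABEL_CODES, MODALITY_ORDER, PAIN_LABELS

N_SENSORS = len(MODALITY_ORDER)

#: The modality-ablation sets compared in the fusion experiment.
MODALITY_SETS: dict[str, tuple[str, ...]] = {
    "all": MODALITY_ORDER,
    "eeg_fe": ("eeg", "fe"),
    "no_eeg_fe": tuple(m for m in MODALITY_ORDER if m not in ("eeg", "fe")),
}


@dataclass(frozen=True)
class FusionWeights:
    """Nonnegative sensor weights on the unit simplex."""

    w: np.ndarray
    modalities: tuple[str, ...] = MODALITY_ORDER

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "w", w)
        if w.shape != (len(self.modalities),):
            raise ValueError("weight length must match modality count")
        if np.any(w < -1e-9) or abs(w.sum() - 1.0) > 1e-6:
            raise ValueError("weights must be nonnegative and sum to 1")

    def as_dict(self) -> dict[str, float]:
        return {m: float(v) for m, v in zip(self.modalities, self.w)}


@dataclass
class GAConfig:
    """Genetic-algorithm settings.

    Defaults use a crossover rate of 0.8, mutation rate 0.02, population
    50 and at most 50 generations; the violation threshold defaults to
    0.5 class-units, half the spacing between adjacent class codes.
    """

    population_size: int = 50
    max_generations: int = 50
    crossover_rate: float = 0.8
    mutation_rate: float = 0.02
    mutation_sd: float = 0.1
    tournament_size: int = 3
    elitism: int = 1
    threshold: float = 0.5
    seed: int = 0
    stop_on_zero_violations: bool = False

    def validate(self) -> None:
        for r in (self.crossover_rate, self.mutation_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        for s in (self.population_size, self.max_generations,
                  self.tournament_size):
            if s < 1:
                raise ValueError("sizes must be >= 1")
        if self.elitism < 0 or self.elitism >= self.population_size:
            raise ValueError("elitism must be in [0, population_size)")


def project_to_simplex(
    w: np.ndarray, active: np.ndarray | None = None
) -> np.ndarray:
    """Clip to nonnegative and renormalize to unit sum.

    Inactive coordinates are forced to zero; a degenerate all-zero vector
    maps to the uniform distribution over active coordinates.
    """
    w = np.asarray(w, dtype=float).copy()
    if active is None:
        active = np.ones(w.shape, dtype=bool)
    w[~active] = 0.0
    w[w < 0] = 0.0
    total = w.sum()
    if total <= 0:
        w[active] = 1.0 / active.sum()
    else:
        w /= total
    return w


def fuse(s: Sequence[float], w: FusionWeights | np.ndarray) -> float:
    """Fused score: weighted sum of the nine sensor scores."""
    s = np.asarray(s, dtype=float)
    wv = w.w if isinstance(w, FusionWeights) else np.asarray(w, dtype=float)
    if s.shape != (N_SENSORS,) or wv.shape != (N_SENSORS,):
        raise ValueError(f"fuse expects {N_SENSORS} scores and weights")
    if not (np.all(np.isfinite(s)) and np.all(np.isfinite(wv))):
        raise ValueError("non-finite inputs")
    return float(s @ wv)


def fitness(
    w: FusionWeights | np.ndarray,
    S: np.ndarray,
    y: np.ndarray,
    threshold: float = 0.5,
) -> tuple[int, float]:
    """(violations, mean absolute error) of fused scores against truth.

    A violation is a window whose |fused - true| exceeds the threshold.
    Fitness ordering is lexicographic: fewer violations first, then lower
    MAE.
    """
    wv = w.w if isinstance(w, FusionWeights) else np.asarray(w, dtype=float)
    S = np.asarray(S, dtype=float)
    y = np.asarray(y, dtype=float)
    if S.shape[0] == 0:
        raise ValueError("empty fusion dataset")
    err = np.abs(S @ wv - y)
    return int(np.sum(err > threshold)), float(err.mean())


def ga_optimize(
    S: np.ndarray,
    y: np.ndarray,
    cfg: GAConfig | None = None,
    active: np.ndarray | None = None,
    track_population: bool = False,
) -> tuple[FusionWeights, list[dict]]:
    """Learn fusion weights by a real-coded genetic algorithm.

    Chromosomes are weight vectors on the simplex (Dirichlet-uniform
    initialization over active sensors).  Per generation: tournament
    selection, arithmetic-blend crossover with probability
    ``crossover_rate``, per-gene Gaussian mutation with probability
    ``mutation_rate``, simplex projection after every operator, and
    elitism.  Runs for ``max_generations`` (optionally stopping as soon
    as the best individual has zero violations, i.e. every fused score is
    within the threshold of the truth — but by default the budget is
    spent refining the MAE tie-break).  Deterministic given the seed.

    Returns the best weights and a per-generation history of best
    ``(violations, mae)``.
    """
    cfg = cfg or GAConfig()
    cfg.validate()
    S = np.asarray(S, dtype=float)
    y = np.asarray(y, dtype=float)
    if S.size == 0 or S.shape[0] != y.shape[0]:
        raise ValueError("fusion dataset empty or misaligned")
    m = S.shape[1]
    if active is None:
        active = np.ones(m, dtype=bool)
    active = np.asarray(active, dtype=bool)
    rng = np.random.default_rng(cfg.seed)

    pop = np.zeros((cfg.population_size, m))
    pop[:, active] = rng.dirichlet(
        np.ones(int(active.sum())), size=cfg.population_size
    )

    def evaluate(P: np.ndarray) -> list[tuple[int, float]]:
        err = np.abs(P @ S.T - y[None, :])
        viol = (err > cfg.threshold).sum(axis=1)
        mae = err.mean(axis=1)
        return list(zip(viol.astype(int), mae.astype(float)))

    history: list[dict] = []
    best_w: np.ndarray | None = None
    best_fit: tuple[int, float] | None = None
    for gen in range(cfg.max_generations):
        fits = evaluate(pop)
        order = sorted(range(len(fits)), key=lambda i: fits[i])
        gen_best = fits[order[0]]
        if best_fit is None or gen_best < best_fit:
            best_fit = gen_best
            best_w = pop[order[0]].copy()
        rec = {"generation": gen, "violations": best_fit[0], "mae": best_fit[1]}
        if track_population:
            rec["population"] = pop.copy()
        history.append(rec)
        if cfg.stop_on_zero_violations and best_fit[0] == 0:
            break
        if gen == cfg.max_generations - 1:
            break

        new = [pop[i].copy() for i in order[: cfg.elitism]]
        while len(new) < cfg.population_size:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, cfg.population_size,
                                          size=cfg.tournament_size)
                winner = min(contenders, key=lambda i: fits[i])
                parents.append(pop[winner].copy())
            c1, c2 = parents
            if rng.uniform() < cfg.crossover_rate:
                u = rng.uniform()
                c1, c2 = u * c1 + (1 - u) * c2, (1 - u) * c1 + u * c2
            for child in (c1, c2):
                mutate = (rng.uniform(size=m) < cfg.mutation_rate) & active
                if mutate.any():
                    child[mutate] += rng.normal(0.0, cfg.mutation_sd,
                                                size=int(mutate.sum()))
                new.append(project_to_simplex(child, active))
        pop = np.asarray(new[: cfg.population_size])

    assert best_w is not None
    return FusionWeights(project_to_simplex(best_w, active)), history


def classify_from_fused(fs) -> np.ndarray | str:
    """Nearest class code to a fused score; midpoints round up (toward
    the higher-pain class) and out-of-range scores clip to the ends."""
    arr = np.asarray(fs, dtype=float)
    codes = np.clip(np.floor(arr + 0.5), 0, 2).astype(int)
    labels = np.asarray(PAIN_LABELS, dtype=object)[codes]
    if np.isscalar(fs) or arr.ndim == 0:
        return str(labels)
    return labels


def sensor_score_matrix(
    models: Mapping[str, "object"],
    features: pd.DataFrame,
    modalities: Sequence[str] = MODALITY_ORDER,
) -> np.ndarray:
    """n x 9 matrix of per-modality cascade scores, in canonical order."""
    from .cascade import modality_columns

    S = np.zeros((len(features), len(modalities)))
    for j, m in enumerate(modalities):
        cols = modality_columns(features.columns, m)
        S[:, j] = predict_score(models[m], features[cols])
    return S


def run_modality_sets(
    features: pd.DataFrame,
    labels,
    subjects,
    sets: Mapping[str, Sequence[str]] | None = None,
    cascade_config: CascadeConfig | None = None,
    ga_config: GAConfig | None = None,
    seed: int = 0,
    test_fraction: float = 0.3,
) -> dict[str, dict]:
    """Fusion ablation: learn weights per modality set, evaluate held out.

    Subjects are split into train/test groups (``test_fraction`` of
    subjects held out); per-modality cascades are trained on the training
    subjects, the GA learns weights on the training score matrix with
    excluded modalities' weights fixed at zero, and each set is evaluated
    on the held-out subjects' fused scores.  Returns, per set, the learned
    weights, the 3x3 confusion matrix (rows true, columns predicted, class
    order B/LP/HP), per-class F1 and macro-F1.
    """
    sets = dict(sets) if sets is not None else dict(MODALITY_SETS)
    ga_config = ga_config or GAConfig(seed=seed)
    y = np.asarray(labels, dtype=object)
    subjects = np.asarray(subjects)
    for name, mods in sets.items():
        unknown = set(mods) - set(MODALITY_ORDER)
        if unknown:
            raise ValueError(f"set {name!r} references unknown modalities {unknown}")

    uniq = np.unique(subjects)
    rng = np.random.default_rng(seed)
    test_subj = set(rng.choice(uniq, size=max(2, int(round(test_fraction * len(uniq)))),
                               replace=False))
    is_test = np.isin(subjects, list(test_subj))
    models = train_per_modality(features[~is_test], y[~is_test], cascade_config)
    S_train = sensor_score_matrix(models, features[~is_test])
    S_test = sensor_score_matrix(models, features[is_test])
    y_train = np.array([LABEL_CODES[v] for v in y[~is_test]], dtype=float)
    y_test = y[is_test]

    results: dict[str, dict] = {}
    for name, mods in sets.items():
        active = np.array([m in mods for m in MODALITY_ORDER])
        weights, history = ga_optimize(S_train, y_train, ga_config, active)
        fused = S_test @ weights.w
        pred = classify_from_fused(fused)
        confusion = pd.DataFrame(
            0, index=list(PAIN_LABELS), columns=list(PAIN_LABELS)
        )
        for t, p in zip(y_test, pred):
            confusion.loc[t, p] += 1
        f1 = f1_per_class(confusion.to_numpy())
        results[name] = {
            "weights": weights,
            "history": history,
            "confusion": confusion,
            "per_class_f1": f1,
            "macro_f1": float(np.mean(list(f1.values()))),
            "n_test": int(is_test.sum()),
        }
    return results
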