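"""Cross-validation, model comparison and expected genetic gain.

Predictive ability (PA) is the Pearson correlation between genotype
least-squares means (eBLUEs, the fixed-effects "observed" values) and
the breeding values predicted for genotypes whose phenotypes were
masked.  Ten-fold cross-validation assigns whole genotypes to folds, so
no record of a validation genotype informs its own prediction.  Models
are compared by Tukey's HSD over repeated runs (compact letter
display), and translated to expected genetic gain per year,
``dG = PA * sigma_a * i / L``, with selection intensity ``i`` and
breeding-cycle length ``L`` in years.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .kinship import RelationshipMatrix
from .model import ModelSpec, build_design, fit_eblue, fit_gibbs

__all__ = [
    "CVResult",
    "GainInputs",
    "make_folds",
    "cross_validate",
    "predictive_ability",
    "expected_genetic_gain",
    "compare_models",
]

#: default breeding-cycle lengths (years): phenotypic and pedigree
#: selection run the full cycle; genomic selection skips one field stage.
DEFAULT_CYCLE_YEARS = {"phenotypic": 12.0, "pedigree": 12.0, "genomic": 9.0}


@dataclass
class CVResult:
    folds: dict[str, int]  # genotype -> fold id
    pa: np.ndarray  # per-fold predictive ability
    mse: np.ndarray  # per-fold mean squared error (centered scales)
    pa_mean: float
    pa_sd: float
    mse_mean: float
    mse_sd: float
    pooled_pa: float
    seed: int


@dataclass
class GainInputs:
    pa: float
    sigma_a: float
    intensity: float = 1.0
    cycle_years: float = 12.0

    def __post_init__(self) -> None:
        if self.cycle_years <= 0:
            raise ValueError("cycle_years must be positive")
        if self.intensity < 0:
            raise ValueError("selection intensity must be >= 0")


def make_folds(ids: list[str], k: int = 10, seed: int = 0) -> dict[str, int]:
    """Random genotype-level partition into ``k`` folds of near-equal size."""
    ids = list(ids)
    if k < 2 or k > len(ids):
        raise ValueError("need 2 <= k <= number of genotypes")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    assignment: dict[str, int] = {}
    for pos, idx in enumerate(order):
        assignment[ids[idx]] = pos % k
    return assignment


def predictive_ability(eblues: np.ndarray, predicted: np.ndarray) -> float:
    """Pearson correlation between eBLUEs and predicted breeding values."""
    a = np.asarray(eblues, float)
    b = np.asarray(predicted, float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need two equal-length vectors with >= 3 entries")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("predictive ability undefined for constant vectors")
    return float(np.corrcoef(a, b)[0, 1])


def cross_validate(
    phenotypes: pd.DataFrame,
    relationship: RelationshipMatrix,
    spec: ModelSpec,
    k: int = 10,
    seed: int = 0,
    folds: dict[str, int] | None = None,
    eblues: pd.Series | None = None,
) -> CVResult:
    """k-fold genotype-masking cross-validation.

    Per fold, every record of the validation genotypes is removed, the
    model is refit on the remainder, and the predicted breeding values
    of the masked genotypes are compared with their (full-data) eBLUEs:
    Pearson correlation per fold, and MSE after centering both vectors
    within the fold (predictions and eBLUEs live on different location
    scales).  Pass the same ``folds`` to several models for paired
    comparisons.
    """
    ph = phenotypes
    if "trait" in ph.columns and ph["trait"].nunique() > 1:
        ph = ph[ph["trait"] == spec.trait]
    ids = sorted(ph["genotype"].astype(str).unique())
    if folds is None:
        folds = make_folds(ids, k=k, seed=seed)
    n_folds = len(set(folds.values()))
    if eblues is None:
        eblues = fit_eblue(ph, spec)

    fold_of = ph["genotype"].astype(str).map(folds)
    spec = replace(spec, relationship=relationship)
    ss = np.random.SeedSequence(seed)
    fold_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n_folds)]

    pa_vals, mse_vals = [], []
    pooled_e, pooled_p = [], []
    for f in range(n_folds):
        val_ids = sorted(g for g, fid in folds.items() if fid == f)
        if len(val_ids) < 3:
            raise ValueError(f"fold {f} has fewer than 3 genotypes")
        train = ph[fold_of != f]
        design = build_design(train, replace(spec, seed=fold_seeds[f]))
        result = fit_gibbs(design)
        pred = result.bv.loc[val_ids].to_numpy()
        obs = eblues.loc[val_ids].to_numpy()
        pa_vals.append(predictive_ability(obs, pred))
        oc, pc = obs - obs.mean(), pred - pred.mean()
        mse_vals.append(float(np.mean((oc - pc) ** 2)))
        pooled_e.append(oc)
        pooled_p.append(pc)

    pa = np.array(pa_vals)
    mse = np.array(mse_vals)
    pooled = float(
        np.corrcoef(np.concatenate(pooled_e), np.concatenate(pooled_p))[0, 1]
    )
    return CVResult(
        folds=dict(folds),
        pa=pa,
        mse=mse,
        pa_mean=float(pa.mean()),
        pa_sd=float(pa.std(ddof=1)) if pa.size > 1 else 0.0,
        mse_mean=float(mse.mean()),
        mse_sd=float(mse.std(ddof=1)) if mse.size > 1 else 0.0,
        pooled_pa=pooled,
        seed=seed,
    )


def expected_genetic_gain(g: GainInputs) -> float:
    """Expected genetic gain per year: ``PA * sigma_a * i / L``."""
    return g.pa * g.sigma_a * g.intensity / g.cycle_years


def compare_models(
    estimates: pd.DataFrame, alpha: float = 0.05
) -> dict[str, str]:
    """Tukey-HSD compact letter display over repeated runs per model.

    ``estimates`` has columns ``model`` and ``value`` (one row per
    independent run).  Models sharing a letter are not significantly
    different at ``alpha``.  Letters are assigned to the maximal
    cliques of the non-significance graph, ordered by decreasing model
    mean, so relabeling models never changes the grouping.
    """
    import networkx as nx
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    models = sorted(estimates["model"].unique())
    if len(models) < 2:
        raise ValueError("need at least two models to compare")
    counts = estimates.groupby("model").size()
    if counts.min() < 2:
        raise ValueError("need at least two runs per model")
    if counts.nunique() != 1:
        raise ValueError("runs per model must be balanced")

    means = estimates.groupby("model")["value"].mean()
    within_ss = float(
        estimates.groupby("model")["value"].transform(lambda v: v - v.mean()).pow(2).sum()
    )
    if within_ss == 0.0:
        # zero within-model variance: models differ iff their means differ
        graph = nx.Graph()
        graph.add_nodes_from(models)
        for i, m1 in enumerate(models):
            for m2 in models[i + 1 :]:
                if np.isclose(means[m1], means[m2]):
                    graph.add_edge(m1, m2)
    else:
        res = pairwise_tukeyhsd(
            endog=estimates["value"].to_numpy(float),
            groups=estimates["model"].to_numpy(),
            alpha=alpha,
        )
        table = pd.DataFrame(
            res.summary().data[1:], columns=res.summary().data[0]
        )
        graph = nx.Graph()
        graph.add_nodes_from(models)
        for _, row in table.iterrows():
            if not bool(row["reject"]):
                graph.add_edge(row["group1"], row["group2"])

    cliques = list(nx.find_cliques(graph))
    cliques.sort(key=lambda c: (-max(means[m] for m in c), sorted(c)))
    letters: dict[str, str] = {m: "" for m in models}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for i, clique in enumerate(cliques):
        for m in clique:
            letters[m] += alphabet[i % len(alphabet)]
    return {m: "".join(sorted(v)) for m, v in letters.items()}
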