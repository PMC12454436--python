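"""Motor-learning (phase) analyses.

The SRTT induces sequence learning: early blocks (default 1-3, the
*learning* phase) and late blocks (default 10-12, *learned*) are
contrasted by (i) cross-phase decoder transfer — a decoder trained on
each phase is tested on held-out trials of both phases — and (ii)
cluster-based permutation statistics on the decoder's latent source time
courses: per component and time point a two-group one-way F statistic
between phases, clusters of adjacent supra-threshold samples scored by
their F mass, and significance assessed against the max-cluster-mass
distribution under random phase-label permutations (exhaustive
enumeration on small instances).  Correction is across time within each
component; no correction across components is applied, since component
counts are reported per subject.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .data import EpochSet
from .decoder import LFCNN, LFCNNHyperparams, latent_sources, remap_task, train
from .interpret import activation_patterns
from .simulate import ConfigurationError


@dataclass(frozen=True)
class PhaseSplit:
    learning_blocks: frozenset[int] = frozenset({1, 2, 3})
    learned_blocks: frozenset[int] = frozenset({10, 11, 12})

    def validate(self) -> None:
        if not self.learning_blocks or not self.learned_blocks:
            raise ConfigurationError("phase block sets must be non-empty")
        if self.learning_blocks & self.learned_blocks:
            raise ConfigurationError("learning and learned block sets overlap")


def split_phases(x: EpochSet, ps: PhaseSplit | None = None) -> tuple[EpochSet, EpochSet]:
    """Partition trials into (learning, learned) epoch sets by block."""
    ps = ps or PhaseSplit()
    ps.validate()
    blocks = np.asarray(x.block)
    m_learning = np.isin(blocks, list(ps.learning_blocks))
    m_learned = np.isin(blocks, list(ps.learned_blocks))
    if not m_learning.any() or not m_learned.any():
        raise ConfigurationError("one of the phases selects no trials")
    return (
        x.select(m_learning, note=f"phase=learning{sorted(ps.learning_blocks)}"),
        x.select(m_learned, note=f"phase=learned{sorted(ps.learned_blocks)}"),
    )


# ---------------------------------------------------------------------------
# F statistics and cluster permutation
# ---------------------------------------------------------------------------

def f_oneway_two_groups(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-group one-way ANOVA F along axis 0, vectorized over the rest.

    ``a`` is (n1, ...), ``b`` is (n2, ...); returns F with df (1, n1+n2-2).
    """
    n1, n2 = a.shape[0], b.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 trials per phase")
    m1, m2 = a.mean(axis=0), b.mean(axis=0)
    gm = (n1 * m1 + n2 * m2) / (n1 + n2)
    ssb = n1 * (m1 - gm) ** 2 + n2 * (m2 - gm) ** 2
    ssw = ((a - m1) ** 2).sum(axis=0) + ((b - m2) ** 2).sum(axis=0)
    dfw = n1 + n2 - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ssb / (ssw / dfw)
    return np.where(np.isfinite(F), F, 0.0)


def _clusters_1d(F: np.ndarray, threshold: float) -> list[tuple[int, int, float]]:
    """Contiguous supra-threshold runs: (start, stop_exclusive, mass)."""
    above = F > threshold
    out = []
    i = 0
    t = F.size
    while i < t:
        if above[i]:
            j = i
            while j < t and above[j]:
                j += 1
            out.append((i, j, float(F[i:j].sum())))
            i = j
        else:
            i += 1
    return out


def _max_mass(F: np.ndarray, threshold: float) -> float:
    cl = _clusters_1d(F, threshold)
    return max((m for _, _, m in cl), default=0.0)


@dataclass
class PhaseContrastResult:
    times: np.ndarray
    F: np.ndarray                      # (k, t) F time courses
    threshold: float
    clusters: list[list[tuple[int, int, float]]]   # per component
    cluster_p: list[np.ndarray]        # per component, one p per cluster
    alpha: float
    n_permutations: int
    similarities: np.ndarray           # one per significant cluster
    significant_components: np.ndarray

    @property
    def n_significant_components(self) -> int:
        return int(self.significant_components.size)

    def cluster_table(self) -> pd.DataFrame:
        rows = []
        dt = self.times[1] - self.times[0] if self.times.size > 1 else 0.0
        for c, (cls, ps) in enumerate(zip(self.clusters, self.cluster_p)):
            for (i, j, mass), p in zip(cls, ps):
                rows.append({
                    "component": c,
                    "start_s": float(self.times[i]),
                    "end_s": float(self.times[j - 1] + dt),
                    "mass": mass,
                    "p": float(p),
                })
        return pd.DataFrame(rows, columns=["component", "start_s", "end_s",
                                           "mass", "p"])


def cluster_permutation_f(
    a: np.ndarray,
    b: np.ndarray,
    threshold: float | None = None,
    n_permutations: int | None = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, float, list, list]:
    """Cluster permutation test between two trial groups.

    ``a``/``b`` are (trials, k, t) latent sources.  Per component, the
    observed F time course is thresholded (default: the F(1, n-2) upper
    ``alpha`` quantile) into clusters scored by mass; the null is the
    per-permutation maximum cluster mass within that component, from
    random phase-label permutations — or from *all* label assignments
    when ``n_permutations`` is None (exhaustive mode, small n only).

    Returns (F, threshold, clusters, cluster_p).
    """
    n1, n2 = a.shape[0], b.shape[0]
    if threshold is None:
        threshold = float(stats.f.ppf(1.0 - alpha, 1, n1 + n2 - 2))
    pooled = np.concatenate([a, b], axis=0)
    F_obs = f_oneway_two_groups(a, b)           # (k, t)
    k = F_obs.shape[0]
    clusters = [_clusters_1d(F_obs[c], threshold) for c in range(k)]

    if n_permutations is None:
        # exhaustive enumeration over all assignments of n1 trials to group 1
        idx_all = np.arange(n1 + n2)
        null = []
        for comb in combinations(idx_all, n1):
            g1 = np.asarray(comb)
            g2 = np.setdiff1d(idx_all, g1, assume_unique=True)
            Fp = f_oneway_two_groups(pooled[g1], pooled[g2])
            null.append([_max_mass(Fp[c], threshold) for c in range(k)])
        null = np.asarray(null)                  # (n_assignments, k)
        n_eff = null.shape[0]
        cluster_p = [
            np.array([float((null[:, c] >= m).mean()) for _, _, m in clusters[c]])
            for c in range(k)
        ]
        return F_obs, threshold, clusters, cluster_p

    rng = np.random.default_rng(seed)
    null = np.empty((n_permutations, k))
    for r in range(n_permutations):
        perm = rng.permutation(n1 + n2)
        Fp = f_oneway_two_groups(pooled[perm[:n1]], pooled[perm[n1:]])
        for c in range(k):
            null[r, c] = _max_mass(Fp[c], threshold)
    cluster_p = [
        np.array([
            float((1 + (null[:, c] >= m).sum()) / (1 + n_permutations))
            for _, _, m in clusters[c]
        ])
        for c in range(k)
    ]
    return F_obs, threshold, clusters, cluster_p


def latent_contrast(
    model: LFCNN,
    x_learning: EpochSet,
    x_learned: EpochSet,
    threshold: float | None = None,
    n_permutations: int | None = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> PhaseContrastResult:
    """Phase contrast on a single decoder's latent sources.

    Both phase datasets pass through the same (e.g. learning-trained)
    decoder; the per-trial temporal-layer output enters the F test.  For
    each significant cluster, the spatial-pattern similarity (cosine)
    between per-phase pattern reconstructions of that component is
    attached.
    """
    a = latent_sources(model, x_learning)
    b = latent_sources(model, x_learned)
    F, thr, clusters, cluster_p = cluster_permutation_f(
        a, b, threshold=threshold, n_permutations=n_permutations,
        alpha=alpha, seed=seed,
    )
    sig_comps = []
    sims = []
    pat_a = activation_patterns(model, x_learning, data_scope="learning")
    pat_b = activation_patterns(model, x_learned, data_scope="learned")
    for c in range(F.shape[0]):
        sig = [p for p in cluster_p[c] if p < alpha]
        if sig:
            sig_comps.append(c)
            for _ in sig:
                sims.append(pattern_similarity(pat_a.A_normed[:, c],
                                               pat_b.A_normed[:, c]))
    return PhaseContrastResult(
        times=x_learning.times, F=F, threshold=thr, clusters=clusters,
        cluster_p=cluster_p, alpha=alpha,
        n_permutations=(0 if n_permutations is None else n_permutations),
        similarities=np.asarray(sims, dtype=float),
        significant_components=np.asarray(sig_comps, dtype=int),
    )


def save_contrast_h5(path, res: PhaseContrastResult) -> None:
    """HDF5 export mirroring the result fields (cluster table goes to CSV
    via :meth:`PhaseContrastResult.cluster_table`)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=res.times)
        f.create_dataset("F", data=res.F)
        f.create_dataset("similarities", data=res.similarities)
        f.create_dataset("significant_components",
                         data=res.significant_components)
        f.attrs["threshold"] = res.threshold
        f.attrs["alpha"] = res.alpha
        f.attrs["n_permutations"] = res.n_permutations
        tab = res.cluster_table()
        for col in tab.columns:   # empty tables default to object dtype
            f.create_dataset(f"clusters/{col}",
                             data=tab[col].to_numpy(dtype=float))


def pattern_similarity(a: np.ndarray, b: np.ndarray, normalized: bool = True) -> float:
    """Scalar product between two spatial-pattern coefficient vectors.

    Normalized (cosine) by default so the value lies in [-1, 1]; the raw
    scalar product is available with ``normalized=False``.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("patterns must have equal length")
    if not normalized:
        return float(a @ b)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-norm pattern")
    return float(a @ b / (na * nb))


# ---------------------------------------------------------------------------
# cross-phase decoding
# ---------------------------------------------------------------------------

def cross_phase_decoding(
    x: EpochSet,
    ps: PhaseSplit | None = None,
    task: str = "four",
    hp: LFCNNHyperparams | None = None,
    seed: int = 0,
    n_outer: int = 6,
    n_inner: int = 5,
) -> pd.DataFrame:
    """2x2 train-phase x test-phase accuracy table for one subject.

    Within each phase a nested-CV decoder set provides same-phase
    accuracy on held-out trials; cross-phase accuracy applies each outer
    fold's model to *all* trials of the other phase and averages over
    folds.  Returns a tidy frame with columns train_phase, test_phase,
    accuracy.
    """
    ps = ps or PhaseSplit()
    x_learning, x_learned = split_phases(x, ps)
    phases = {"learning": x_learning, "learned": x_learned}
    for name, xp in phases.items():
        y, _ = remap_task(xp.labels, task)
        counts = np.bincount(y)
        if counts.min() < n_outer:
            raise ConfigurationError(
                f"phase {name!r}: smallest class has {counts.min()} trials, "
                f"need >= {n_outer}"
            )
    rows = []
    for train_name, xp in phases.items():
        res = train(xp, task=task, hp=hp, seed=seed, n_outer=n_outer,
                    n_inner=n_inner)
        rows.append({"train_phase": train_name, "test_phase": train_name,
                     "accuracy": res.mean_accuracy})
        other_name = "learned" if train_name == "learning" else "learning"
        other = phases[other_name]
        y_other, mask_other = remap_task(other.labels, task)
        X_other = other.data[mask_other]
        accs = [float((m.predict(X_other) == y_other).mean()) for m in res.models]
        rows.append({"train_phase": train_name, "test_phase": other_name,
                     "accuracy": float(np.mean(accs))})
    return pd.DataFrame(rows)


def phase_transfer_tests(tables: list[pd.DataFrame], alpha: float = 0.05) -> pd.DataFrame:
    """Paired t-tests over subjects for the four phase-transfer comparisons.

    ``tables`` holds one 2x2 accuracy frame (from
    :func:`cross_phase_decoding`) per subject.
    """
    if len(tables) < 2:
        raise ValueError("paired tests require at least 2 subjects")

    def acc(tab, tr, te):
        row = tab[(tab.train_phase == tr) & (tab.test_phase == te)]
        return float(row["accuracy"].iloc[0])

    cells = {
        (tr, te): np.array([acc(t, tr, te) for t in tables])
        for tr in ("learning", "learned") for te in ("learning", "learned")
    }
    comparisons = [
        (("learning", "learning"), ("learning", "learned")),
        (("learned", "learned"), ("learned", "learning")),
        (("learning", "learning"), ("learned", "learning")),
        (("learned", "learned"), ("learning", "learned")),
    ]
    rows = []
    for a_cell, b_cell in comparisons:
        a, b = cells[a_cell], cells[b_cell]
        if np.allclose(a, b):
            tstat, p = 0.0, 1.0
        else:
            tstat, p = stats.ttest_rel(a, b)
        rows.append({
            "a": "->".join(a_cell), "b": "->".join(b_cell),
            "mean_a": float(a.mean()), "mean_b": float(b.mean()),
            "t": float(tstat), "p": float(p), "significant": bool(p < alpha),
        })
    return pd.DataFrame(rows)
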