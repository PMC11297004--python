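"""Cross-model energy re-ranking of sampled minima.

Given a database of minima explored under one potential, how does a second
potential (a different parameter set, or the same parameters with a
perturbed solvent screening) order those same structures?  Rank
correlations (Kendall τ-b, Spearman ρ) over a random or energy-stratified
sample of minima quantify the agreement; discordant pairs pinpoint where
the two models disagree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import kendalltau, spearmanr

from .exceptions import ContractViolation, PotentialEvaluationError, UndefinedCorrelationError
from .ktn import KTN
from .optim import local_minimise

__all__ = ["RankComparison", "sample_minima", "rescore", "rank_correlation"]


@dataclass
class RankComparison:
    """Agreement between two energy orderings of one sample of minima."""

    sample: list
    energies_a: np.ndarray
    energies_b: np.ndarray
    kendall_tau: float
    spearman_rho: float
    n_discordant_pairs: int
    discordant_pairs: list = field(default_factory=list)  # [(id_i, id_j)]
    failed_members: list = field(default_factory=list)


def sample_minima(
    ktn: KTN, n: int, rng_seed: int = 0, stratify_by_energy: bool = False
) -> list:
    """Reproducible random sample of ``n`` minimum ids.

    With ``stratify_by_energy`` the energy range is split into tertiles and
    the sample drawn evenly across them (padding from the remainder when a
    tertile is too small).
    """
    ids = sorted(ktn.minima)
    if n > len(ids):
        raise ContractViolation(f"sample size {n} exceeds {len(ids)} minima")
    rng = np.random.default_rng(rng_seed)
    if not stratify_by_energy:
        return sorted(int(i) for i in rng.choice(ids, size=n, replace=False))

    energies = np.array([ktn.minima[i].energy for i in ids])
    lo, hi = energies.min(), energies.max()
    edges = [lo, lo + (hi - lo) / 3, lo + 2 * (hi - lo) / 3, np.inf]
    per = n // 3
    chosen: list[int] = []
    leftovers: list[int] = []
    for t in range(3):
        members = [
            i for i, e in zip(ids, energies) if edges[t] <= e < edges[t + 1]
        ]
        take = min(per if t < 2 else n - 2 * per, len(members))
        picked = rng.choice(members, size=take, replace=False) if take else []
        chosen.extend(int(i) for i in picked)
        leftovers.extend(m for m in members if m not in set(map(int, picked)))
    while len(chosen) < n:
        extra = leftovers.pop(int(rng.integers(len(leftovers))))
        chosen.append(int(extra))
    return sorted(chosen)


def rescore(
    sample: list,
    ktn: KTN,
    model_b,
    reminimise: bool = False,
    tol: float = 1e-6,
) -> tuple[np.ndarray, list]:
    """Energies of the sampled minima under ``model_b``.

    Single-point energies on the stored geometries by default, so both
    models are compared on identical structures; with ``reminimise`` each
    geometry is first relaxed under ``model_b``.  Members whose evaluation
    fails are excluded and reported in the second return value.
    """
    energies, failed = [], []
    for mid in sample:
        x = ktn.minima[mid].coordinates
        try:
            if reminimise:
                energies.append(local_minimise(model_b, x, tol=tol).energy)
            else:
                e = model_b.energy(x)
                if not np.isfinite(e):
                    raise PotentialEvaluationError("non-finite energy", x)
                energies.append(float(e))
        except Exception:
            failed.append(mid)
            energies.append(np.nan)
    return np.array(energies), failed


def _discordant_pairs(sample, a, b):
    out = []
    for i in range(len(a)):
        for j in range(i + 1, len(a)):
            if (a[i] - a[j]) * (b[i] - b[j]) < 0:
                out.append((sample[i], sample[j]))
    return out


def rank_correlation(
    energies_a, energies_b, sample: list | None = None
) -> RankComparison:
    """Kendall τ-b and Spearman ρ between two energy vectors.

    Ties are handled by the tie-corrected τ-b; the discordant-pair list is
    retained for reporting.  A constant vector has no defined ranking and
    raises :class:`UndefinedCorrelationError`.
    """
    a = np.asarray(energies_a, dtype=float)
    b = np.asarray(energies_b, dtype=float)
    if a.size != b.size:
        raise ContractViolation("energy vectors differ in length")
    if a.size < 2:
        raise ContractViolation("need at least two minima to compare ranks")
    sample = list(sample) if sample is not None else list(range(a.size))
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    kept = [s for s, good in zip(sample, ok) if good]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedCorrelationError(
            "rank correlation undefined for a constant energy vector"
        )
    tau = float(kendalltau(a, b, variant="b").statistic)
    rho = float(spearmanr(a, b).statistic)
    disc = _discordant_pairs(kept, a, b)
    return RankComparison(
        sample=kept,
        energies_a=a,
        energies_b=b,
        kendall_tau=tau,
        spearman_rho=rho,
        n_discordant_pairs=len(disc),
        discordant_pairs=disc,
        failed_members=[s for s, good in zip(sample, ok) if not good],
    )
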