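"""Two-sample analyses.

Shared/private clonotype comparison with a coefficient of determination on
log10 frequencies, and convergent-recombination analysis (how many distinct
nucleotide sequences encode each amino-acid clonotype in each sample).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import Repertoire, ValidationError


@dataclass(slots=True)
class OverlapResult:
    """Shared and private clonotypes of a sample pair.

    ``r_squared`` is the squared Pearson correlation of shared-clone
    frequencies (log10 by default); it is None with ``r_squared_reason`` set
    when fewer than 3 clones are shared or a frequency vector is constant.
    """

    sample_a: str
    sample_b: str
    key_mode: str
    shared: list[tuple[tuple[str, ...], float, float]]
    only_a: list[tuple[tuple[str, ...], float]]
    only_b: list[tuple[tuple[str, ...], float]]
    r_squared: float | None
    r_squared_reason: str | None = None
    log_scale: bool = True

    @property
    def n_shared(self) -> int:
        return len(self.shared)


def overlap_pair(
    rep_a: Repertoire,
    rep_b: Repertoire,
    key_mode: str = "nt+vj",
    log_scale: bool = True,
) -> OverlapResult:
    """Exact-match join of two repertoires on the clonotype key.

    Both repertoires are re-keyed to ``key_mode`` before matching.  The
    coefficient of determination is computed over shared clones on log10
    frequencies (``log_scale=False`` switches to raw frequencies).
    Self-comparison is permitted but warned about.
    """
    if rep_a.sample_id == rep_b.sample_id:
        warnings.warn(
            f"comparing sample {rep_a.sample_id!r} with itself", stacklevel=2
        )
    a = rep_a.rekey(key_mode)
    b = rep_b.rekey(key_mode)
    fa = a.freq_by_key()
    fb = b.freq_by_key()

    shared = [(k, fa[k], fb[k]) for k in fa if k in fb]
    shared.sort(key=lambda t: (-(t[1] + t[2]), t[0]))
    only_a = sorted(
        ((k, v) for k, v in fa.items() if k not in fb), key=lambda t: (-t[1], t[0])
    )
    only_b = sorted(
        ((k, v) for k, v in fb.items() if k not in fa), key=lambda t: (-t[1], t[0])
    )

    r2: float | None = None
    reason: str | None = None
    if len(shared) < 3:
        reason = f"only {len(shared)} shared clonotypes (need >= 3)"
    else:
        x = np.array([t[1] for t in shared])
        y = np.array([t[2] for t in shared])
        if log_scale:
            x, y = np.log10(x), np.log10(y)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            reason = "constant frequency vector"
        else:
            r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
    return OverlapResult(
        sample_a=a.sample_id,
        sample_b=b.sample_id,
        key_mode=key_mode,
        shared=shared,
        only_a=only_a,
        only_b=only_b,
        r_squared=r2,
        r_squared_reason=reason,
        log_scale=log_scale,
    )


@dataclass(slots=True)
class UnsharedDistribution:
    """Private clonotypes of each sample, ranked by descending frequency."""

    table_a: pd.DataFrame
    table_b: pd.DataFrame
    max_private_freq_a: float
    max_private_freq_b: float


def _ranked_private(entries: list[tuple[tuple[str, ...], float]]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rank": range(1, len(entries) + 1),
            "key": ["|".join(k) for k, _ in entries],
            "freq": [v for _, v in entries],
        }
    )


def unshared_distribution(result: OverlapResult) -> UnsharedDistribution:
    """Ranked private-clonotype tables for both samples of an overlap."""
    ta = _ranked_private(result.only_a)
    tb = _ranked_private(result.only_b)
    return UnsharedDistribution(
        table_a=ta,
        table_b=tb,
        max_private_freq_a=float(ta["freq"].max()) if len(ta) else 0.0,
        max_private_freq_b=float(tb["freq"].max()) if len(tb) else 0.0,
    )


@dataclass(slots=True)
class ConvergenceResult:
    """Nucleotide degeneracy of amino-acid clonotypes in a sample pair.

    ``per_aa`` rows are (cdr3_aa, nt variants in A, nt variants in B, pooled
    distinct variants).  ``degree_histogram`` maps pooled variant count ->
    number of aa clonotypes; ``hist_a``/``hist_b`` are the per-sample
    histograms over aa clonotypes present in that sample.
    """

    scope: str
    per_aa: list[tuple[str, int, int, int]]
    degree_histogram: dict[int, int]
    hist_a: dict[int, int] = field(default_factory=dict)
    hist_b: dict[int, int] = field(default_factory=dict)


def convergence_pair(
    rep_a: Repertoire, rep_b: Repertoire, scope: str = "shared_aa"
) -> ConvergenceResult:
    """Count distinct CDR3 nucleotide sequences per amino-acid clonotype.

    ``scope`` selects which amino-acid clonotypes are tabulated:
    ``shared_aa`` (present in both samples — the default) or ``all_aa``
    (union).  Input repertoires must be nucleotide-keyed so that distinct
    synonymous variants are still distinguishable.
    """
    for rep in (rep_a, rep_b):
        if rep.key_mode.startswith("aa"):
            raise ValidationError(
                f"sample {rep.sample_id!r} is aa-keyed ({rep.key_mode}); "
                "convergence analysis needs nt-level tables (nt or nt+vj)"
            )
    if scope not in ("shared_aa", "all_aa"):
        raise ValidationError(f"scope must be 'shared_aa' or 'all_aa', got {scope!r}")

    variants_a: dict[str, set[str]] = {}
    variants_b: dict[str, set[str]] = {}
    for rep, table in ((rep_a, variants_a), (rep_b, variants_b)):
        for rec in rep.records:
            table.setdefault(rec.cdr3_aa, set()).add(rec.cdr3_nt)

    if scope == "shared_aa":
        aa_set = sorted(set(variants_a) & set(variants_b))
    else:
        aa_set = sorted(set(variants_a) | set(variants_b))

    per_aa = []
    degree: dict[int, int] = {}
    hist_a: dict[int, int] = {}
    hist_b: dict[int, int] = {}
    for aa in aa_set:
        na = len(variants_a.get(aa, set()))
        nb = len(variants_b.get(aa, set()))
        pooled = len(variants_a.get(aa, set()) | variants_b.get(aa, set()))
        per_aa.append((aa, na, nb, pooled))
        degree[pooled] = degree.get(pooled, 0) + 1
        if na:
            hist_a[na] = hist_a.get(na, 0) + 1
        if nb:
            hist_b[nb] = hist_b.get(nb, 0) + 1
    return ConvergenceResult(
        scope=scope,
        per_aa=per_aa,
        degree_histogram=dict(sorted(degree.items())),
        hist_a=dict(sorted(hist_a.items())),
        hist_b=dict(sorted(hist_b.items())),
    )
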