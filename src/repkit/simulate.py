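"""Synthetic clonotype-table generator.

Produces repertoires with controlled clonal-expansion structure (power-law,
lognormal or uniform clone abundances), V/J usage biases, a CDR3 length
spectrum, programmable convergent recombination (synonymous nucleotide
variants of the same amino-acid CDR3), a non-productive fraction, and
longitudinal expansion/contraction scripts.  Everything is reproducible
from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

from .model import ClonotypeRecord, Repertoire, ValidationError, build_repertoire

_BASES = "ACGT"
_CODON_TABLE = unambiguous_dna_by_id[1]

# codon -> synonymous codons differing only at the third position
_SYNONYMOUS_THIRD: dict[str, list[str]] = {}
for _codon, _aa in _CODON_TABLE.forward_table.items():
    _SYNONYMOUS_THIRD[_codon] = [
        _codon[:2] + b
        for b in _BASES
        if b != _codon[2] and _CODON_TABLE.forward_table.get(_codon[:2] + b) == _aa
    ]

_STOP_CODONS = tuple(sorted(_CODON_TABLE.stop_codons))


def translate(nt: str) -> str:
    """Standard-genetic-code translation; stops appear as ``*``."""
    if len(nt) % 3:
        raise ValidationError(f"sequence length {len(nt)} not a multiple of 3")
    return str(Seq(nt).translate())


DEFAULT_V_USAGE = {
    "TRBV5-8": 0.08, "TRBV6-2": 0.10, "TRBV7-9": 0.12, "TRBV9": 0.10,
    "TRBV13": 0.08, "TRBV18": 0.07, "TRBV19": 0.15, "TRBV20-1": 0.10,
    "TRBV27": 0.12, "TRBV28": 0.08,
}
DEFAULT_J_USAGE = {
    "TRBJ1-1": 0.14, "TRBJ1-2": 0.10, "TRBJ1-5": 0.12, "TRBJ2-1": 0.18,
    "TRBJ2-3": 0.14, "TRBJ2-5": 0.16, "TRBJ2-7": 0.16,
}
# unimodal spectrum over in-frame lengths, centred on 45 nt
DEFAULT_LENGTH_DIST = {
    30: 0.02, 33: 0.05, 36: 0.09, 39: 0.14, 42: 0.18,
    45: 0.20, 48: 0.14, 51: 0.10, 54: 0.08,
}

ABUNDANCE_MODELS = ("power_law", "lognormal", "uniform")


def _check_prob_map(name: str, mapping: dict) -> None:
    vals = np.array(list(mapping.values()), dtype=float)
    if len(vals) == 0 or (vals < 0).any() or abs(vals.sum() - 1.0) > 1e-9:
        raise ValidationError(
            f"{name}: probabilities must be non-negative and sum to 1 "
            f"(got sum {vals.sum() if len(vals) else 0})"
        )


@dataclass(slots=True)
class SimulationParams:
    """Knobs of the repertoire generator; see module docstring."""

    n_clones: int = 200
    depth: int = 10_000
    abundance_model: str = "power_law"
    alpha: float = 1.0  # power-law exponent over clone rank
    sigma: float = 1.0  # lognormal spread
    v_usage: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_V_USAGE))
    j_usage: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_J_USAGE))
    cdr3_nt_length_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_DIST)
    )
    convergence_rate: float = 0.0
    nonproductive_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_clones < 1:
            raise ValidationError(f"n_clones must be >= 1, got {self.n_clones}")
        if self.depth < 1:
            raise ValidationError(f"depth must be >= 1, got {self.depth}")
        if self.abundance_model not in ABUNDANCE_MODELS:
            raise ValidationError(
                f"unknown abundance model {self.abundance_model!r}; "
                f"choose from {ABUNDANCE_MODELS}"
            )
        _check_prob_map("v_usage", self.v_usage)
        _check_prob_map("j_usage", self.j_usage)
        _check_prob_map("cdr3_nt_length_distribution", self.cdr3_nt_length_distribution)
        for length in self.cdr3_nt_length_distribution:
            if length <= 0 or length % 3:
                raise ValidationError(
                    f"cdr3 lengths must be positive multiples of 3, got {length}"
                )
        if not 0.0 <= self.convergence_rate <= 1.0:
            raise ValidationError("convergence_rate must be in [0, 1]")
        if not 0.0 <= self.nonproductive_fraction <= 1.0:
            raise ValidationError("nonproductive_fraction must be in [0, 1]")


@dataclass(slots=True)
class CloneTemplate:
    """Ground-truth identity of one simulated clone (pre-sampling)."""

    cdr3_nt: str
    cdr3_aa: str
    v_gene: str
    j_gene: str
    parent: int | None = None  # index of the clone this is a synonymous variant of


def _sample_choice(rng: np.random.Generator, mapping: dict) -> object:
    keys = list(mapping)
    probs = np.array([mapping[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return keys[rng.choice(len(keys), p=probs)]


def _random_cdr3(rng: np.random.Generator, length: int, existing: set[str]) -> str:
    """Random in-frame sequence, rejecting chance stop codons so that
    non-productive clones are exactly the scripted fraction."""
    while True:
        nt = "".join(_BASES[b] for b in rng.integers(0, 4, size=length))
        if nt in existing:
            continue
        if any(nt[i : i + 3] in _STOP_CODONS for i in range(0, length, 3)):
            continue
        return nt


def _synonymous_variant(
    rng: np.random.Generator, nt: str, existing: set[str]
) -> str | None:
    """A distinct nucleotide sequence translating to the same amino acids.

    Mutates the third position of one codon to a synonymous alternative.
    Returns None when no codon admits a synonymous swap (all ATG/TGG/stops).
    """
    codon_starts = [
        i for i in range(0, len(nt), 3) if _SYNONYMOUS_THIRD.get(nt[i : i + 3])
    ]
    if not codon_starts:
        return None
    order = rng.permutation(len(codon_starts))
    for oi in order:
        i = codon_starts[int(oi)]
        alternatives = list(_SYNONYMOUS_THIRD[nt[i : i + 3]])
        rng.shuffle(alternatives)
        for alt in alternatives:
            cand = nt[:i] + alt + nt[i + 3 :]
            if cand not in existing:
                return cand
    return None


def _abundance_weights(params: SimulationParams, rng: np.random.Generator) -> np.ndarray:
    n = params.n_clones
    if params.abundance_model == "power_law":
        w = np.arange(1, n + 1, dtype=float) ** (-params.alpha)
    elif params.abundance_model == "lognormal":
        w = np.exp(rng.normal(0.0, params.sigma, size=n))
    else:
        w = np.ones(n)
    return w / w.sum()


def _make_templates(
    params: SimulationParams, rng: np.random.Generator
) -> list[CloneTemplate]:
    n = params.n_clones
    n_convergent = int(round(params.convergence_rate * n))
    n_base = n - n_convergent
    if n_base < 1:
        raise ValidationError("convergence_rate too high: no base clones left")
    existing: set[str] = set()
    templates: list[CloneTemplate] = []
    for _ in range(n_base):
        length = int(_sample_choice(rng, params.cdr3_nt_length_distribution))
        nt = _random_cdr3(rng, length, existing)
        existing.add(nt)
        templates.append(
            CloneTemplate(
                cdr3_nt=nt,
                cdr3_aa=translate(nt),
                v_gene=str(_sample_choice(rng, params.v_usage)),
                j_gene=str(_sample_choice(rng, params.j_usage)),
            )
        )
    # non-productive clones: plant an in-frame stop in a random base clone
    n_stop = int(round(params.nonproductive_fraction * n_base))
    stop_idx = rng.choice(n_base, size=n_stop, replace=False) if n_stop else []
    for idx in stop_idx:
        t = templates[int(idx)]
        pos = int(rng.integers(0, len(t.cdr3_nt) // 3)) * 3
        stop = _STOP_CODONS[int(rng.integers(0, len(_STOP_CODONS)))]
        existing.discard(t.cdr3_nt)
        t.cdr3_nt = t.cdr3_nt[:pos] + stop + t.cdr3_nt[pos + 3 :]
        t.cdr3_aa = translate(t.cdr3_nt)
        existing.add(t.cdr3_nt)
    # convergent clones: synonymous variant of a random productive base clone
    productive = [i for i, t in enumerate(templates) if "*" not in t.cdr3_aa]
    if n_convergent and not productive:
        raise ValidationError("cannot add convergent variants: no productive clones")
    for _ in range(n_convergent):
        for _attempt in range(100):
            pi = int(productive[int(rng.integers(0, len(productive)))])
            variant = _synonymous_variant(rng, templates[pi].cdr3_nt, existing)
            if variant is not None:
                break
        else:
            raise ValidationError("failed to generate a synonymous variant")
        existing.add(variant)
        parent = templates[pi]
        templates.append(
            CloneTemplate(
                cdr3_nt=variant,
                cdr3_aa=parent.cdr3_aa,
                v_gene=parent.v_gene,
                j_gene=parent.j_gene,
                parent=pi,
            )
        )
    return templates


def _draw_repertoire(
    templates: Sequence[CloneTemplate],
    weights: np.ndarray,
    depth: int,
    rng: np.random.Generator,
    sample_id: str,
) -> Repertoire:
    counts = rng.multinomial(depth, weights)
    records = [
        ClonotypeRecord(
            cdr3_nt=t.cdr3_nt,
            cdr3_aa=t.cdr3_aa,
            v_gene=t.v_gene,
            j_gene=t.j_gene,
            count=int(c),
        )
        for t, c in zip(templates, counts)
        if c > 0
    ]
    return build_repertoire(records, "nt+vj", sample_id=sample_id)


def degeneracy_truth(rep: Repertoire) -> dict[str, set[str]]:
    """Ground-truth aa -> distinct nt sets of a simulated repertoire."""
    truth: dict[str, set[str]] = {}
    for rec in rep.records:
        truth.setdefault(rec.cdr3_aa, set()).add(rec.cdr3_nt)
    return truth


def simulate_repertoire(
    params: SimulationParams, sample_id: str = "sim"
) -> Repertoire:
    """Draw one repertoire: clone identities, abundances, multinomial reads.

    Reads always sum to ``depth`` exactly; clones drawn to zero reads are
    dropped.  The convergent fraction of clones are synonymous third-position
    variants of earlier clones (same amino-acid CDR3, same V/J).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    templates = _make_templates(params, rng)
    weights = _abundance_weights(params, rng)
    # decouple abundance rank from generation order
    weights = weights[rng.permutation(len(templates))]
    return _draw_repertoire(templates, weights, params.depth, rng, sample_id)


@dataclass(slots=True)
class TimepointSpec:
    label: str
    fold_changes: dict[int, float] = field(default_factory=dict)  # clone index -> fold


@dataclass(slots=True)
class LongitudinalScript:
    """Base repertoire plus per-timepoint clonal fold changes."""

    base: SimulationParams
    timepoints: list[TimepointSpec]

    def validate(self) -> None:
        self.base.validate()
        if not self.timepoints:
            raise ValidationError("at least one timepoint required")
        for tp in self.timepoints:
            for idx, fold in tp.fold_changes.items():
                if not 0 <= idx < self.base.n_clones:
                    raise ValidationError(
                        f"timepoint {tp.label!r}: clone id {idx} outside "
                        f"[0, {self.base.n_clones})"
                    )
                if fold <= 0:
                    raise ValidationError(
                        f"timepoint {tp.label!r}: fold change must be > 0, got {fold}"
                    )


def simulate_longitudinal(script: LongitudinalScript) -> list[Repertoire]:
    """Draw one repertoire per timepoint from a shared clone pool.

    Clone nucleotide identities are generated once, so tracking and overlap
    find the same clonotypes at every timepoint.  Each timepoint multiplies
    the base abundance of the scripted clones by its fold change,
    renormalizes, and re-draws reads multinomially.  Fold-change indices
    refer to abundance rank (0 = most abundant base clone).
    """
    script.validate()
    params = script.base
    rng = np.random.default_rng(params.seed)
    templates = _make_templates(params, rng)
    base_weights = _abundance_weights(params, rng)
    # here clone index IS abundance rank: no permutation, so scripts can
    # target "the i-th most abundant clone" directly
    reps = []
    for tp in script.timepoints:
        w = base_weights.copy()
        for idx, fold in tp.fold_changes.items():
            w[idx] *= fold
        w = w / w.sum()
        reps.append(_draw_repertoire(templates, w, params.depth, rng, tp.label))
    return reps
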