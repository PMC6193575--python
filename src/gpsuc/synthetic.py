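"""Self-contained synthetic data: proteins, labelled sites, pseudo-profiles.

The generator emulates the statistical structure of succinylation
training sets: background protein sequences carrying many lysines, a
subset of which are designated modified ("positive") sites whose flanks
are enriched for charged residues (E, K, R, D) — the compositional bias
observed around real succinylation sites. The enrichment strength is a
single ``effect_size`` dial: 0 gives a pure null model (positives are
statistically exchangeable with negatives), 1 rewrites every motif
position of every positive flank from the motif distribution.

Profiles are deterministic substitution-table pseudo-profiles, so the
whole pipeline — encoding, selection, channel training, fusion and
evaluation — runs with no external search or download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .alphabet import CANONICAL
from .profiles import PssmProfile, pseudo_profile, write_pssm
from .seqio import (
    NEGATIVE,
    POSITIVE,
    ProteinRecord,
    SiteLabel,
    write_fasta,
    write_sites,
)

__all__ = [
    "SyntheticSpec",
    "generate",
    "write_dataset",
    "generate_channel_scores",
    "SWISSPROT_COMPOSITION",
    "DEFAULT_MOTIF",
]

#: Swiss-Prot-like background residue frequencies (percent, canonical order),
#: bundled as constants so no download is needed.
SWISSPROT_COMPOSITION: dict[str, float] = {
    "A": 8.25, "C": 1.38, "D": 5.45, "E": 6.72, "F": 3.86,
    "G": 7.07, "H": 2.27, "I": 5.91, "K": 5.80, "L": 9.65,
    "M": 2.41, "N": 4.06, "P": 4.74, "Q": 3.93, "R": 5.53,
    "S": 6.65, "T": 5.36, "V": 6.85, "W": 1.10, "Y": 2.92,
}

#: Charged-residue flank preference around positive sites, applied at
#: offsets ±1..±8 from the central lysine.
DEFAULT_MOTIF: dict[int, dict[str, float]] = {
    off: {"E": 0.35, "K": 0.25, "R": 0.20, "D": 0.20}
    for off in (*range(-8, 0), *range(1, 9))
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic succinylation dataset.

    ``effect_size`` is the per-position probability that a motif offset
    of a positive flank is drawn from the motif preference instead of
    the background; 0 is the null model. ``positive_fraction`` is the
    probability that a background lysine is designated a positive site.
    """

    n_proteins: int = 160
    length_range: tuple[int, int] = (80, 160)
    background: Mapping[str, float] | None = None  # None = uniform over 20
    motif: Mapping[int, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_MOTIF
    )
    effect_size: float = 1.0
    positive_fraction: float = 1.0 / 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.effect_size <= 1.0:
            raise ValueError("effect_size must lie in [0, 1]")
        if not 0.0 < self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must lie in (0, 1]")
        if self.n_proteins < 1 or self.length_range[0] < 1:
            raise ValueError("need at least one protein of positive length")


def _background_probs(spec: SyntheticSpec) -> np.ndarray:
    if spec.background is None:
        return np.full(len(CANONICAL), 1.0 / len(CANONICAL))
    probs = np.array([spec.background.get(aa, 0.0) for aa in CANONICAL], float)
    if probs.sum() <= 0:
        raise ValueError("background composition sums to zero")
    return probs / probs.sum()


def generate(
    spec: SyntheticSpec,
) -> tuple[list[ProteinRecord], list[SiteLabel], dict[str, PssmProfile]]:
    """Draw a labelled synthetic dataset from a :class:`SyntheticSpec`.

    Every positive site is a lysine whose flanking motif offsets are
    biased with strength ``effect_size``; every other lysine in the
    generated sequences is a negative site. Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    bg = _background_probs(spec)
    letters = np.array(list(CANONICAL))
    motif_dists = {
        off: (np.array(list(pref)), np.array(list(pref.values()), float))
        for off, pref in spec.motif.items()
    }
    records: list[ProteinRecord] = []
    sites: list[SiteLabel] = []
    any_positive = False
    for p in range(spec.n_proteins):
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        seq = list(rng.choice(letters, size=length, p=bg))
        k_positions = [i for i, aa in enumerate(seq) if aa == "K"]
        chosen = {
            i for i in k_positions if rng.random() < spec.positive_fraction
        }
        for centre in sorted(chosen):
            for off, (res, weights) in motif_dists.items():
                pos = centre + off
                if not 0 <= pos < length or pos in chosen:
                    continue
                if rng.random() < spec.effect_size:
                    seq[pos] = str(rng.choice(res, p=weights / weights.sum()))
        pid = f"SYN{p:04d}"
        sequence = "".join(seq)
        records.append(ProteinRecord(id=pid, sequence=sequence))
        for i, aa in enumerate(sequence):
            if aa != "K":
                continue
            label = POSITIVE if i in chosen else NEGATIVE
            any_positive = any_positive or label == POSITIVE
            sites.append(SiteLabel(pid, i + 1, label))
    if not any_positive:
        raise ValueError(
            "infeasible spec: no positive lysine placements were generated"
        )
    profiles = {rec.id: pseudo_profile(rec) for rec in records}
    return records, sites, profiles


def write_dataset(
    records: Sequence[ProteinRecord],
    sites: Sequence[SiteLabel],
    profiles: Mapping[str, PssmProfile],
    directory: str | Path,
) -> dict[str, Path]:
    """Emit the package's own FASTA / sites-TSV / PSSM-directory formats."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fasta = directory / "proteins.fasta"
    tsv = directory / "sites.tsv"
    pssm_dir = directory / "pssm"
    pssm_dir.mkdir(exist_ok=True)
    write_fasta(records, fasta)
    write_sites(sites, tsv)
    by_id = {rec.id: rec for rec in records}
    for pid, profile in profiles.items():
        write_pssm(profile, pssm_dir / f"{pid}.pssm", by_id[pid].sequence)
    return {"fasta": fasta, "sites": tsv, "pssm_dir": pssm_dir}


def generate_channel_scores(
    beta: Sequence[float],
    alpha: float,
    n: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate channel scores with labels drawn from the fusion model.

    Scores are i.i.d. uniform on [0, 1] per channel; each label is +1
    with probability sigmoid(S·beta + alpha). Used for fusion-coefficient
    recovery checks.
    """
    rng = np.random.default_rng(seed)
    beta = np.asarray(beta, dtype=float)
    S = rng.uniform(size=(n, beta.size))
    p = 1.0 / (1.0 + np.exp(-(S @ beta + alpha)))
    labels = np.where(rng.uniform(size=n) < p, 1, -1)
    return S, labels
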