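"""Synthetic protein N-termini with the grammar the classifier must learn.

Three classes are generated:

* ``sp`` — secretory proteins: an initiator M, then a positively charged
  n-region (1-5 residues, K/R mixed with neutral residues), a hydrophobic
  h-region (7-15 residues), and a polar c-region (3-7 residues) whose -3
  and -1 positions before the cleavage site carry a small residue (A),
  followed by a mature region of background composition.  Residues up to
  the cleavage site are labelled S, the rest N.  With default ranges the
  signal peptide spans 11-27 residues after the initiator M.
* ``tm`` — transmembrane negatives: a hydrophobic helix of 15-25 residues
  starting within the first 70 positions, labelled T, everything else N.
  These mimic signal peptides (long hydrophobic stretch) and are the hard
  negatives the FPR_TM index tracks.
* ``other`` — soluble negatives of background composition, labelled all N.

The generator emulates the compositional grammar only — no organism-specific
residue frequencies, no homology structure, no mixed SP+TM topologies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ALPHABET, ProteinRecord

CHARGED = "KR"
NEUTRAL = "STGNQA"
HYDROPHOBIC = "AILFVWM"
POLAR = "STGNQ"
#: probability that an n-region residue is charged rather than neutral
N_REGION_CHARGED_P = 0.6


@dataclass(frozen=True)
class SyntheticSpec:
    n_sp: int = 0
    n_tm: int = 0
    n_other: int = 0
    n_region_len: tuple[int, int] = (1, 5)
    h_region_len: tuple[int, int] = (7, 15)
    c_region_len: tuple[int, int] = (3, 7)
    tm_helix_len: tuple[int, int] = (15, 25)
    tm_start_max: int = 70
    mature_len: tuple[int, int] = (30, 150)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_region_len", "h_region_len", "c_region_len",
            "tm_helix_len", "mature_len",
        ):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ValueError(f"{name}: invalid range [{lo}, {hi}]")
        if self.c_region_len[0] < 3:
            raise ValueError("c-region must have >= 3 residues for the (-3,-1) pattern")
        if self.tm_helix_len[1] > self.tm_start_max:
            raise ValueError("tm helix cannot fit inside the first tm_start_max positions")
        if min(self.n_sp, self.n_tm, self.n_other) < 0:
            raise ValueError("class counts must be non-negative")


def _draw(rng: np.random.Generator, alphabet: str, n: int) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=n))


def _rint(rng: np.random.Generator, lo_hi: tuple[int, int]) -> int:
    return int(rng.integers(lo_hi[0], lo_hi[1] + 1))


def generate_protein(
    cls: str, spec: SyntheticSpec, rng: np.random.Generator, rid: str = "syn"
) -> ProteinRecord:
    """Generate one labelled record of class ``sp``, ``tm`` or ``other``."""
    if cls == "sp":
        n_len = _rint(rng, spec.n_region_len)
        h_len = _rint(rng, spec.h_region_len)
        c_len = _rint(rng, spec.c_region_len)
        n_region = "".join(
            _draw(rng, CHARGED, 1) if rng.random() < N_REGION_CHARGED_P
            else _draw(rng, NEUTRAL, 1)
            for _ in range(n_len)
        )
        h_region = _draw(rng, HYDROPHOBIC, h_len)
        c_list = list(_draw(rng, POLAR, c_len))
        c_list[-3] = "A"
        c_list[-1] = "A"
        c_region = "".join(c_list)
        mature = _draw(rng, ALPHABET, _rint(rng, spec.mature_len))
        seq = "M" + n_region + h_region + c_region + mature
        sp_len = 1 + n_len + h_len + c_len
        labels = "S" * sp_len + "N" * len(mature)
    elif cls == "tm":
        helix_len = _rint(rng, spec.tm_helix_len)
        start = int(rng.integers(1, spec.tm_start_max - helix_len + 1))
        prefix = "M" + _draw(rng, ALPHABET, start - 1)
        helix = _draw(rng, HYDROPHOBIC, helix_len)
        tail = _draw(rng, ALPHABET, _rint(rng, spec.mature_len))
        seq = prefix + helix + tail
        labels = "N" * start + "T" * helix_len + "N" * len(tail)
    elif cls == "other":
        seq = "M" + _draw(rng, ALPHABET, _rint(rng, spec.mature_len))
        labels = "N" * len(seq)
    else:
        raise ValueError(f"unknown class {cls!r}")
    return ProteinRecord(id=rid, sequence=seq, labels=labels)


def generate_dataset(spec: SyntheticSpec) -> list[ProteinRecord]:
    """Generate a shuffled labelled dataset with the requested class counts."""
    total = spec.n_sp + spec.n_tm + spec.n_other
    if total < 1:
        raise ValueError("at least one record must be requested")
    rng = np.random.default_rng(spec.seed)
    records: list[ProteinRecord] = []
    for cls, count in (("sp", spec.n_sp), ("tm", spec.n_tm), ("other", spec.n_other)):
        for i in range(count):
            records.append(generate_protein(cls, spec, rng, rid=f"{cls}_{i:05d}"))
    order = rng.permutation(total)
    return [records[i] for i in order]
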