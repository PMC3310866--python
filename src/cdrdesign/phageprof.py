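"""Experimental amino-acid preference statistics from selection sequences.

Phage-display selections randomize 5-residue CDR windows with the NNK
degenerate codon (N = A/C/G/T, K = G/T: 32 codons, all 20 amino acids plus
the amber stop).  Binding variants are counted per position and compared with
the NNK-encoded background probability p_i through a Bayesian pseudo-counted
log-odds in half-bit units:

    W_ji = 2 * log2( ((C_ji + sqrt(M) p_i) / (M + sqrt(M))) / p_i )

where C_ji is the count of type i at position j and M the number of selected
sequences covering j.  The binary preference label is the sign: deltaW = 1
iff W >= 0, equivalently iff the observed count reaches the expected count
M p_i.  Positional information content I_j uses the same pseudo-counted
frequencies against the NNK background.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table

from .aminoacids import AA1

__all__ = [
    "SelectionDataset",
    "nnk_background",
    "nnk_codon_counts",
    "count_profile",
    "experimental_preference",
    "information_content",
    "preference_profile",
    "read_sequences",
]


def nnk_codon_counts() -> dict[str, int]:
    """Codon multiplicity per amino acid (1-letter, '*' for stop) over the 32
    NNK codons."""
    counts: dict[str, int] = {}
    table = standard_dna_table.forward_table
    for b1, b2, b3 in product("ACGT", "ACGT", "GT"):
        codon = b1 + b2 + b3
        aa = table.get(codon, "*")
        counts[aa] = counts.get(aa, 0) + 1
    return counts


def nnk_background(stop_policy: str = "amber_to_Gln") -> pd.Series:
    """NNK background probabilities over the 20 amino-acid types.

    ``amber_to_Gln``: the single amber stop (TAG) is read as Gln, as in supE
    suppressor phage hosts.  ``renormalize_over_20``: the stop codon is
    dropped and the 31 sense codons renormalized.
    """
    counts = nnk_codon_counts()
    if stop_policy == "amber_to_Gln":
        counts["Q"] = counts.get("Q", 0) + counts.pop("*", 0)
        denom = 32.0
    elif stop_policy == "renormalize_over_20":
        counts.pop("*", None)
        denom = float(sum(counts.values()))
    else:
        raise ValueError(f"unknown stop_policy {stop_policy!r}")
    p = pd.Series({aa: counts.get(aa, 0) / denom for aa in AA1}, name="p")
    return p / p.sum()


@dataclass
class SelectionDataset:
    """Equal-length CDR window sequences from one selection library."""

    library_id: str
    positions: list[str]
    sequences: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        width = len(self.positions)
        for idx, seq in enumerate(self.sequences):
            if len(seq) != width:
                raise ValueError(
                    f"sequence {idx} has length {len(seq)}, expected {width}")
            bad = set(seq.upper()) - set(AA1)
            if bad:
                raise ValueError(
                    f"sequence {idx} ({seq!r}): letters outside the 20-type "
                    f"alphabet: {sorted(bad)}")
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def m(self) -> int:
        return len(self.sequences)


def count_profile(dataset: SelectionDataset) -> pd.DataFrame:
    """Exact per-(position, type) counts; duplicates count separately.

    Returns a tidy frame with columns position, aa, C, M.
    """
    m = dataset.m
    rows = []
    for col, pos in enumerate(dataset.positions):
        counts = {aa: 0 for aa in AA1}
        for seq in dataset.sequences:
            counts[seq[col]] += 1
        for aa in AA1:
            rows.append({"position": pos, "aa": aa, "C": counts[aa], "M": m})
    return pd.DataFrame(rows)


def experimental_preference(c, m, p):
    """Half-bit preference W and binary label deltaW from counts.

    Vectorized over ``c``/``p``; ``m`` is the per-position sample size.
    """
    c = np.asarray(c, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any(m < 1):
        raise ValueError("M must be >= 1")
    if np.any(p <= 0):
        raise ValueError("background probabilities must be positive")
    pseudo = np.sqrt(m)
    q = (c + pseudo * p) / (m + pseudo)
    w = 2.0 * np.log2(q / p)
    return w, (w >= 0).astype(int)


def information_content(c, m, p) -> float:
    """Positional information content I_j = sum_i q_i log2(q_i / p_i) with the
    pseudo-counted frequencies q; non-negative by Gibbs' inequality."""
    c = np.asarray(c, dtype=float)
    p = np.asarray(p, dtype=float)
    pseudo = np.sqrt(m)
    q = (c + pseudo * p) / (m + pseudo)
    q = q / q.sum()
    return float(np.sum(q * np.log2(q / p)))


def preference_profile(
    dataset: SelectionDataset, background: pd.Series | None = None
) -> pd.DataFrame:
    """Full preference profile: C, M, W, deltaW per (position, type) and the
    positional information content I."""
    p = background if background is not None else nnk_background()
    prof = count_profile(dataset)
    pvec = p.reindex(list(AA1)).to_numpy()
    out = []
    for pos, grp in prof.groupby("position", sort=False):
        grp = grp.set_index("aa").reindex(list(AA1))
        c = grp["C"].to_numpy(float)
        m = int(grp["M"].iloc[0])
        w, dw = experimental_preference(c, m, pvec)
        i_j = information_content(c, m, pvec)
        for aa, ci, wi, dwi in zip(AA1, c, w, dw):
            out.append({"position": pos, "aa": aa, "C": int(ci), "M": m,
                        "p": p[aa], "W": wi, "deltaW": int(dwi), "I": i_j})
    return pd.DataFrame(out)


def read_sequences(text: str, library_id: str, positions) -> SelectionDataset:
    """Read window sequences from FASTA or two-column TSV (library_id, seq).

    TSV rows for other libraries are ignored.
    """
    text = text.strip()
    seqs: list[str] = []
    if text.startswith(">"):
        for rec in SeqIO.parse(io.StringIO(text), "fasta"):
            seqs.append(str(rec.seq))
    else:
        for ln in text.splitlines():
            if not ln.strip() or ln.startswith("#"):
                continue
            parts = ln.split("\t")
            if len(parts) == 1:
                seqs.append(parts[0].strip())
            elif parts[0].strip() == library_id:
                seqs.append(parts[1].strip())
    return SelectionDataset(library_id=library_id, positions=[str(p) for p in positions],
                            sequences=seqs)
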