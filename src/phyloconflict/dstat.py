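"""ABBA-BABA introgression test: site-pattern counting, the D-statistic, and
a delete-one block-jackknife Z score.

Sites are polarized by the outgroup: at each biallelic site the outgroup
allele is ancestral ("A") and the other allele derived ("B").  ABBA sites are
those where P2 and P3 share the derived allele while P1 and the outgroup are
ancestral; BABA sites are those where P1 and P3 share it.  Counting is
frequency-weighted so that populations may hold several sequences: with
derived-allele frequencies p1, p2, p3,

    ABBA = (1 - p1) * p2 * p3        BABA = p1 * (1 - p2) * p3

which reduce to 0/1 indicators with one sequence per population.  Under
incomplete lineage sorting alone E[ABBA] = E[BABA] and D ~ 0; an excess of
one pattern (|Z| >= 3 by convention) indicates gene flow.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GroupedAlignment",
    "DStatResult",
    "count_patterns",
    "d_statistic",
    "jackknife_z",
    "abba_baba",
    "read_popmap",
    "write_popmap",
]

POPULATIONS = ("P1", "P2", "P3", "O")
_BASE_CODE = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T; anything else is missing


@dataclass
class GroupedAlignment:
    """Equal-length aligned sequences with population assignments P1/P2/P3/O."""

    sequences: dict[str, str]
    populations: dict[str, str]

    def __post_init__(self):
        if not self.sequences:
            raise ValueError("empty alignment")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError(f"sequences differ in length: {sorted(lengths)}")
        unknown = set(self.populations.values()) - set(POPULATIONS)
        if unknown:
            raise ValueError(f"unknown population labels: {sorted(unknown)}")
        missing = set(self.sequences) - set(self.populations)
        if missing:
            raise ValueError(f"sequences without a population: {sorted(missing)}")
        for pop in POPULATIONS:
            if not self.members(pop):
                raise ValueError(f"population {pop} has no sequences")

    @property
    def n_sites(self) -> int:
        return len(next(iter(self.sequences.values())))

    def members(self, pop: str) -> list[str]:
        return sorted(n for n in self.sequences if self.populations.get(n) == pop)

    def codes(self, pop: str) -> np.ndarray:
        """(n_members, n_sites) uint8 array; 255 marks a missing/ambiguous base."""
        rows = []
        for name in self.members(pop):
            raw = np.frombuffer(self.sequences[name].upper().encode("ascii"), np.uint8)
            code = np.full(raw.shape, 255, dtype=np.uint8)
            for b, c in _BASE_CODE.items():
                code[raw == b] = c
            rows.append(code)
        return np.stack(rows)

    @classmethod
    def from_fasta(cls, fasta_path, popmap: dict[str, str]) -> "GroupedAlignment":
        seqs = {
            rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")
        }
        return cls(seqs, {n: popmap[n] for n in seqs if n in popmap})

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(s), id=name, description="")
            for name, s in sorted(self.sequences.items())
        ]
        SeqIO.write(records, str(path), "fasta")


def read_popmap(path) -> dict[str, str]:
    """Two-column TSV ``sequence<TAB>P1|P2|P3|O``."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, pop = line.split("\t")
            out[name] = pop
    return out


def write_popmap(path, popmap: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, pop in sorted(popmap.items()):
            fh.write(f"{name}\t{pop}\n")


@dataclass
class DStatResult:
    """ABBA/BABA sums, D, block-jackknife standard error and Z."""

    abba_sum: float
    baba_sum: float
    d: float | None
    n_informative_sites: int
    n_blocks: int = 0
    block_size_sites: int = 0
    jackknife_se: float = math.nan
    z: float | None = None
    d_defined: bool = True
    z_defined: bool = True
    per_block: "np.ndarray | None" = field(default=None, repr=False)


def count_patterns(aln: GroupedAlignment) -> tuple[np.ndarray, np.ndarray]:
    """Per-site ABBA and BABA weights (zero at non-informative sites).

    A site is used only if the outgroup is monomorphic and non-missing, the
    site is biallelic over all non-missing bases, and every ingroup
    population retains at least one non-missing sequence.  Within an ingroup
    population, missing sequences are dropped from that site's frequency.
    """
    pop_codes = {pop: aln.codes(pop) for pop in POPULATIONS}
    n = aln.n_sites

    out = pop_codes["O"]
    out_ok = (out != 255).all(axis=0) & (out == out[0]).all(axis=0)
    anc = out[0].astype(np.int64)

    present = np.zeros((4, n), dtype=bool)
    for codes in pop_codes.values():
        for a in range(4):
            present[a] |= (codes == a).any(axis=0)
    biallelic = present.sum(axis=0) == 2
    # derived allele = the non-ancestral member of the allele pair
    allele_sum = (present * np.arange(4)[:, None]).sum(axis=0)
    der = allele_sum - anc

    freqs = {}
    pop_ok = np.ones(n, dtype=bool)
    for pop in ("P1", "P2", "P3"):
        codes = pop_codes[pop]
        non_missing = (codes != 255).sum(axis=0)
        pop_ok &= non_missing > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[pop] = (codes == der[None, :]).sum(axis=0) / non_missing

    ok = out_ok & biallelic & pop_ok
    p1, p2, p3 = (np.where(ok, freqs[p], 0.0) for p in ("P1", "P2", "P3"))
    abba = np.where(ok, (1.0 - p1) * p2 * p3, 0.0)
    baba = np.where(ok, p1 * (1.0 - p2) * p3, 0.0)
    return abba, baba


def d_statistic(abba_sum: float, baba_sum: float) -> float | None:
    """D = (ABBA - BABA) / (ABBA + BABA); None when the denominator is zero."""
    denom = abba_sum + baba_sum
    if denom <= 0:
        return None
    return (abba_sum - baba_sum) / denom


def jackknife_z(
    abba: np.ndarray, baba: np.ndarray, n_blocks: int = 50
) -> DStatResult:
    """Delete-one block jackknife over contiguous equal-size site blocks.

    Each pseudo-value D_(-i) is D recomputed without block i;
    SE^2 = ((m - 1)/m) * sum_i (D_(-i) - mean)^2 and Z = D / SE.  If fewer
    informative sites than blocks exist the block count is reduced with a
    warning; a zero SE leaves Z undefined and flagged.
    """
    abba = np.asarray(abba, dtype=float)
    baba = np.asarray(baba, dtype=float)
    if abba.shape != baba.shape or abba.ndim != 1:
        raise ValueError("per-site weight arrays must be 1-D and equal length")
    informative = (abba > 0) | (baba > 0)
    n_inf = int(informative.sum())
    if n_blocks < 2:
        raise ValueError("need at least 2 jackknife blocks")
    if 0 < n_inf < n_blocks:
        warnings.warn(
            f"only {n_inf} informative sites; reducing blocks from {n_blocks}",
            RuntimeWarning,
            stacklevel=2,
        )
        n_blocks = max(2, n_inf)

    abba_sum = float(abba.sum())
    baba_sum = float(baba.sum())
    d_full = d_statistic(abba_sum, baba_sum)
    block_size = int(math.ceil(abba.size / n_blocks))
    if d_full is None:
        return DStatResult(
            abba_sum, baba_sum, None, n_inf, n_blocks, block_size,
            d_defined=False, z_defined=False,
        )

    blocks_a = [b.sum() for b in np.array_split(abba, n_blocks)]
    blocks_b = [b.sum() for b in np.array_split(baba, n_blocks)]
    loo = []
    for i in range(n_blocks):
        a = abba_sum - blocks_a[i]
        b = baba_sum - blocks_b[i]
        di = d_statistic(a, b)
        loo.append(d_full if di is None else di)
    loo = np.asarray(loo)
    m = n_blocks
    se = math.sqrt((m - 1) / m * float(((loo - loo.mean()) ** 2).sum()))
    if se == 0.0:
        return DStatResult(
            abba_sum, baba_sum, d_full, n_inf, n_blocks, block_size,
            jackknife_se=0.0, z=None, z_defined=False, per_block=loo,
        )
    return DStatResult(
        abba_sum, baba_sum, d_full, n_inf, n_blocks, block_size,
        jackknife_se=se, z=d_full / se, per_block=loo,
    )


def abba_baba(aln: GroupedAlignment, n_blocks: int = 50) -> DStatResult:
    """Count patterns, compute D, and attach the block-jackknife Z."""
    abba, baba = count_patterns(aln)
    return jackknife_z(abba, baba, n_blocks=n_blocks)
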