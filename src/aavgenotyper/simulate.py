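"""Synthetic genotype-structured recombinant populations.

The generator emulates the statistical structure the genotyping analysis
relies on: a handful of clades ("genotypes") separated by ~11-16% rep
nucleotide distance, members within a clade a few percent apart,
ubiquitous segment-swapping (recombination) between members of the same
genotype inside the rep region, and between-genotype recombination
confined to the cap region. Each simulated population comes with a truth
log (genotype labels and every recombination event), so cluster recovery,
PDCP/PDDM ordering and assignment can all be scored against ground truth
without any external dataset.

Sequence evolution is deliberately minimal: independent per-site
substitution to one of the three alternative bases, no indels, no rate
heterogeneity — sufficient to control expected p-distances, which is all
the downstream statistics consume.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .distance import DistanceMatrix
from .msa import Msa, Region

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a simulated population.

    Defaults mirror the study conditions: a 4400-column gap-free genome
    alignment with the classification (rep-analog) region at columns
    453-1700 and the capsid-analog region at 2250-4400; 4 genotypes of
    30/40/20/13 members (103 sequences); ancestor p-distance ~0.13;
    members ~0.05 apart within a genotype; on average one within-genotype
    rep recombination event and 0.5 unrestricted cap events per sequence.
    """

    genome_length: int = 4400
    rep_region: Region = Region(453, 1700)
    cap_region: Region = Region(2250, 4400)
    n_genotypes: int = 4
    seqs_per_genotype: tuple[int, ...] = (30, 40, 20, 13)
    between_divergence: float = 0.13
    within_divergence: float = 0.05
    rep_recomb_rate: float = 1.0
    cap_recomb_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rep_region.end > self.genome_length or self.cap_region.end > self.genome_length:
            raise ValueError("regions must lie within genome_length")
        a, b = sorted([self.rep_region, self.cap_region])
        if a.end >= b.start:
            raise ValueError("rep and cap regions must not overlap")
        if not (0.0 < self.within_divergence < self.between_divergence < 0.75):
            raise ValueError(
                "need 0 < within_divergence < between_divergence < 0.75"
            )
        if len(self.seqs_per_genotype) != self.n_genotypes:
            raise ValueError("seqs_per_genotype must list one count per genotype")
        if any(c <= 0 for c in self.seqs_per_genotype):
            raise ValueError("all genotype sizes must be positive")
        if self.rep_recomb_rate < 0 or self.cap_recomb_rate < 0:
            raise ValueError("recombination rates must be non-negative")

    @property
    def n_sequences(self) -> int:
        return int(sum(self.seqs_per_genotype))


@dataclass(frozen=True)
class RecombinationEvent:
    recipient: str
    donor: str
    start: int  # alignment columns, 1-based inclusive
    end: int
    region: str  # "rep" | "cap"


@dataclass
class SimTruth:
    """Ground truth of a simulated population."""

    genotype: dict[str, int]  # id -> 1-based genotype number
    events: list[RecombinationEvent] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "genotype": self.genotype,
                    "events": [asdict(e) for e in self.events],
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        raw = json.loads(Path(path).read_text())
        return cls(
            genotype={k: int(v) for k, v in raw["genotype"].items()},
            events=[RecombinationEvent(**e) for e in raw["events"]],
        )


def ancestor_substitution_rate(target_pairwise: float) -> float:
    """Per-lineage substitution probability giving a target pairwise distance.

    Two lineages independently substitute each site with probability q to a
    uniform alternative base. They then agree at a site with probability
    (1-q)^2 + q^2/3, so the expected pairwise distance is 2q - (4/3)q^2;
    invert that for q.
    """
    if not (0.0 < target_pairwise < 0.75):
        raise ValueError("target pairwise distance must be in (0, 0.75)")
    return (2.0 - math.sqrt(4.0 - 16.0 * target_pairwise / 3.0)) / (8.0 / 3.0)


def _mutate(seq: np.ndarray, q: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    hit = np.flatnonzero(rng.random(seq.size) < q)
    if hit.size:
        out[hit] = (out[hit] + rng.integers(1, 4, size=hit.size)) % 4
    return out


def simulate_population(config: SimConfig) -> tuple[Msa, SimTruth]:
    """Simulate a genotype-structured recombinant population.

    Procedure: a uniform random root; per-genotype ancestors derived by
    independent substitution calibrated so ancestor pairs sit near
    ``between_divergence``; members substituted at ``within_divergence/2``
    from their ancestor; then per sequence a Poisson number of segment
    transfers in rep (donor restricted to the same genotype) and in cap
    (donor unrestricted), breakpoints uniform within the region. Output is
    gap-free; the same seed reproduces the population byte for byte.
    """
    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    root = rng.integers(0, 4, size=L, dtype=np.int64)
    q_anc = ancestor_substitution_rate(config.between_divergence)
    ancestors = [_mutate(root, q_anc, rng) for _ in range(config.n_genotypes)]

    ids: list[str] = []
    genomes: list[np.ndarray] = []
    genotype: dict[str, int] = {}
    q_within = config.within_divergence / 2.0
    for g, count in enumerate(config.seqs_per_genotype, start=1):
        for k in range(count):
            sid = f"G{g}_S{k + 1:03d}"
            ids.append(sid)
            genomes.append(_mutate(ancestors[g - 1], q_within, rng))
            genotype[sid] = g

    events: list[RecombinationEvent] = []
    seqs = np.vstack(genomes)
    by_genotype = {
        g: [i for i, sid in enumerate(ids) if genotype[sid] == g]
        for g in range(1, config.n_genotypes + 1)
    }

    def transfer(i: int, donor_pool: list[int], region: Region, tag: str,
                 rate: float) -> None:
        pool = [d for d in donor_pool if d != i]
        if not pool:
            return
        for _ in range(rng.poisson(rate)):
            donor = pool[rng.integers(len(pool))]
            b = np.sort(rng.integers(region.start, region.end + 1, size=2))
            lo, hi = int(b[0]), int(b[1])
            seqs[i, lo - 1 : hi] = seqs[donor, lo - 1 : hi]
            events.append(
                RecombinationEvent(ids[i], ids[donor], lo, hi, tag)
            )

    all_idx = list(range(len(ids)))
    for i in range(len(ids)):
        transfer(i, by_genotype[genotype[ids[i]]], config.rep_region, "rep",
                 config.rep_recomb_rate)
        transfer(i, all_idx, config.cap_region, "cap", config.cap_recomb_rate)

    letters = _BASES[seqs]
    msa = Msa(ids, [row.tobytes().decode("ascii") for row in letters])
    return msa, SimTruth(genotype=genotype, events=events)


# ---------------------------------------------------------------------------
# Published reference-serotype distance table for the rep region (453-1700).
# Upper triangle: nucleotide p-distances; lower triangle: inferred amino
# acid p-distances, as printed (2 decimals). Order as printed.

TABLE1_LABELS = [
    "AAV1", "AAV2", "AAV3", "AAV4", "AAV6", "AAV7",
    "AAV8", "AAV10", "AAV11", "AAV12", "AAV13",
]

_TABLE1_NT_UPPER = [
    [0.16, 0.12, 0.11, 0.02, 0.03, 0.04, 0.05, 0.05, 0.12, 0.12],  # AAV1
    [0.14, 0.14, 0.15, 0.15, 0.16, 0.16, 0.15, 0.14, 0.14],        # AAV2
    [0.05, 0.13, 0.12, 0.13, 0.12, 0.12, 0.13, 0.05],              # AAV3
    [0.12, 0.12, 0.13, 0.12, 0.12, 0.13, 0.03],                    # AAV4
    [0.05, 0.06, 0.07, 0.06, 0.13, 0.13],                          # AAV6
    [0.03, 0.05, 0.04, 0.12, 0.12],                                # AAV7
    [0.05, 0.05, 0.13, 0.14],                                      # AAV8
    [0.01, 0.13, 0.13],                                            # AAV10
    [0.12, 0.13],                                                  # AAV11
    [0.13],                                                        # AAV12
]

_TABLE1_AA_LOWER = [
    [0.17],                                                        # AAV2
    [0.16, 0.18],                                                  # AAV3
    [0.14, 0.19, 0.06],                                            # AAV4
    [0.02, 0.18, 0.16, 0.15],                                      # AAV6
    [0.03, 0.16, 0.16, 0.15, 0.04],                                # AAV7
    [0.05, 0.18, 0.18, 0.16, 0.05, 0.03],                          # AAV8
    [0.07, 0.17, 0.16, 0.16, 0.08, 0.07, 0.07],                    # AAV10
    [0.07, 0.16, 0.16, 0.15, 0.07, 0.06, 0.06, 0.02],              # AAV11
    [0.15, 0.19, 0.19, 0.17, 0.15, 0.14, 0.16, 0.16, 0.16],        # AAV12
    [0.15, 0.18, 0.06, 0.02, 0.15, 0.15, 0.16, 0.16, 0.15, 0.18],  # AAV13
]


def _symmetrize_upper(rows: list[list[float]], n: int) -> np.ndarray:
    m = np.zeros((n, n))
    for i, row in enumerate(rows):
        for off, v in enumerate(row, start=1):
            m[i, i + off] = m[i + off, i] = v
    return m


def table1_fixture() -> DistanceMatrix:
    """The printed 11-serotype rep-region nucleotide distance matrix.

    Upper-triangle values symmetrised; site counts are unknown for a
    printed table, so ``comparable_sites`` is None.
    """
    return DistanceMatrix(
        list(TABLE1_LABELS),
        _symmetrize_upper(_TABLE1_NT_UPPER, len(TABLE1_LABELS)),
    )


def table1_aa_fixture() -> DistanceMatrix:
    """The printed amino-acid companion matrix (lower triangle symmetrised)."""
    n = len(TABLE1_LABELS)
    m = np.zeros((n, n))
    for i, row in enumerate(_TABLE1_AA_LOWER, start=1):
        for j, v in enumerate(row):
            m[i, j] = m[j, i] = v
    return DistanceMatrix(list(TABLE1_LABELS), m)
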