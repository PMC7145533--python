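"""Synthetic readset generator: the download-free test substrate.

Real inputs to the blot are whole-genome read mappings from public
archives; this module emulates the stoichiometric regimes such readsets
display, per gene:

PRESENT_SINGLE      single-copy mt locus, n-fold ≈ 1
PRESENT_DUPLICATED  duplicated mt region, n-fold ≈ 2
PLASTID_INSERT      plastid-derived insert cross-mapped by plastid reads,
                    n-fold ≈ 20 (mt genomes sit well below plastid depth)
PSEUDOGENE_PARTIAL  partial locus: a contiguous 5′ block at n-fold 1,
                    the rest deleted (exon-loss style decay)
NUCLEAR_RESIDUAL    nuclear copy only, n-fold ≈ 0.01 (mt DNA is enriched
                    roughly a hundredfold over nuclear in total DNA)
ABSENT              no homologous sequence at all
LOW_COVERAGE_SET    readset-level regime: shallow controls (depth 8),
                    under which absence cannot be called confidently

Per-position depth is Poisson(control_depth × target n-fold) inside the
covered 5′ block and 0 outside; pileup base counts are drawn from the
truth base with a symmetric 1% error rate. A fixed seed yields
byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from . import io as mio
from .model import ClassifierConfig, DepthProfile, GeneModel, PileupColumn, Tier

__all__ = [
    "Scenario",
    "SCENARIO_DEFAULTS",
    "SimulatedReadset",
    "make_panel",
    "simulate_readset",
    "expected_tier",
    "simulate_scenario_suite",
    "example_readset",
]

#: scenario name -> (target n-fold, covered fraction)
SCENARIO_DEFAULTS: dict[str, tuple[float, float]] = {
    "PRESENT_SINGLE": (1.0, 1.0),
    "PRESENT_DUPLICATED": (2.0, 1.0),
    "PLASTID_INSERT": (20.0, 1.0),
    "PSEUDOGENE_PARTIAL": (1.0, 0.6),
    "NUCLEAR_RESIDUAL": (0.01, 1.0),
    "ABSENT": (0.0, 0.0),
    "LOW_COVERAGE_SET": (0.0, 0.0),
}

#: control depth used for the shallow-readset regime (below the >15 rule)
LOW_COVERAGE_CONTROL_DEPTH = 8.0

_ERROR_RATE = 0.01
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
_STOPS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class Scenario:
    """One gene's simulated stoichiometric regime."""

    name: str
    target_nfold: float
    covered_fraction: float
    noise: str = "poisson"

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_DEFAULTS:
            raise ValueError(f"unknown scenario {self.name!r}")
        if not 0 <= self.covered_fraction <= 1:
            raise ValueError("covered_fraction must be in [0,1]")
        if self.target_nfold < 0:
            raise ValueError("target_nfold must be >= 0")
        if self.noise != "poisson":
            raise ValueError("only poisson noise is implemented")

    @classmethod
    def default(cls, name: str) -> "Scenario":
        nfold, frac = SCENARIO_DEFAULTS[name]
        return cls(name=name, target_nfold=nfold, covered_fraction=frac)


@dataclass
class SimulatedReadset:
    """A complete synthetic readset with its ground truth."""

    readset_id: str
    models: list[GeneModel]
    profiles: dict[str, DepthProfile]
    pileups: dict[str, list[PileupColumn]]
    truth_cds: dict[str, str]
    truth_tiers: dict[str, Tier]
    control_depth: float
    seed: int

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the fixture bundle (BED, depth, pileup, CDS FASTA, labels)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "models": outdir / "models.bed",
            "depth": outdir / "depth.tsv",
            "pileup": outdir / "pileup.tsv",
            "truth_cds": outdir / "truth_cds.fasta",
            "truth_labels": outdir / "truth_labels.tsv",
        }
        with open(paths["models"], "w") as fh:
            for m in self.models:
                for s, e in m.intervals:
                    fh.write(f"{m.seq_id}\t{s}\t{e}\t{m.gene_id}\t0\t{m.strand}\t{m.role}\n")
        mio.write_depth_table(self.profiles, self.models, paths["depth"])
        mio.write_pileup_table(self.pileups, paths["pileup"])
        mio.write_fasta(self.truth_cds, paths["truth_cds"])
        with open(paths["truth_labels"], "w", encoding="utf-8") as fh:
            fh.write("readset_id\tgene_id\tscenario_tier\n")
            for gene, tier in self.truth_tiers.items():
                fh.write(f"{self.readset_id}\t{gene}\t{tier.symbol}\n")
        return paths


def make_panel(
    query_genes: Mapping[str, int],
    controls: Mapping[str, int] | None = None,
) -> list[GeneModel]:
    """Build a gene panel: each gene a single exon on its own reference.

    ``controls`` defaults to the usual trio (matR, nad7, nad4) at 1800 bp.
    """
    if controls is None:
        controls = {g: 1800 for g in mio.DEFAULT_CONTROL_GENES}
    models = [
        GeneModel(g, f"ref_{g}", ((0, L),), "+", "control", True)
        for g, L in controls.items()
    ]
    models += [
        GeneModel(g, f"ref_{g}", ((0, L),), "+", "query", True)
        for g, L in query_genes.items()
    ]
    return models


def expected_tier(scenario: Scenario, cfg: ClassifierConfig = ClassifierConfig()) -> Tier:
    """Truth label the classifier should recover for a scenario.

    Fully covered present regimes carry an intact frame at ample depth →
    FIRST; the partial pseudogene keeps its heat value above the
    third-tier cutoff but breaks continuity and the frame → THIRD;
    nuclear residuals and true absence fail the depth gate → ABSENT; a
    gene absent from a shallow readset (controls below the control_min
    rule) → AMBIGUOUS.
    """
    name = scenario.name
    if name in ("PRESENT_SINGLE", "PRESENT_DUPLICATED", "PLASTID_INSERT"):
        return Tier.FIRST
    if name == "PSEUDOGENE_PARTIAL":
        heat = scenario.target_nfold * scenario.covered_fraction
        if heat > cfg.heat_min and scenario.covered_fraction < 1.0:
            return Tier.THIRD
        return Tier.ABSENT
    if name == "NUCLEAR_RESIDUAL":
        return Tier.ABSENT
    if name == "ABSENT":
        return Tier.ABSENT
    return Tier.AMBIGUOUS  # LOW_COVERAGE_SET


def simulate_readset(
    genes: Sequence[GeneModel],
    scenarios: Mapping[str, Scenario],
    control_depth: float = 40.0,
    seed: int = 0,
    readset_id: Optional[str] = None,
    cfg: ClassifierConfig = ClassifierConfig(),
) -> SimulatedReadset:
    """Simulate one readset over a gene panel.

    Every gene needs a scenario except controls, which are forced to
    PRESENT_SINGLE; a scenario naming an unknown gene is an error.
    """
    by_id = {m.gene_id: m for m in genes}
    unknown = set(scenarios) - set(by_id)
    if unknown:
        raise ValueError(f"scenarios for unknown genes: {sorted(unknown)}")
    for m in genes:
        if m.role == "control":
            sc = scenarios.get(m.gene_id)
            if sc is not None and sc.name != "PRESENT_SINGLE":
                raise ValueError(f"control gene {m.gene_id!r} must be PRESENT_SINGLE")

    rid = readset_id or f"sim{seed}"
    rng = np.random.default_rng(seed)
    profiles: dict[str, DepthProfile] = {}
    pileups: dict[str, list[PileupColumn]] = {}
    truth_cds: dict[str, str] = {}
    truth_tiers: dict[str, Tier] = {}

    for m in genes:
        scenario = (
            Scenario.default("PRESENT_SINGLE")
            if m.role == "control"
            else scenarios.get(m.gene_id, Scenario.default("PRESENT_SINGLE"))
        )
        L = m.length
        truth = _random_cds(rng, L)
        covered = int(round(scenario.covered_fraction * L))
        lam = control_depth * scenario.target_nfold
        depths = np.zeros(L, dtype=np.int64)
        if covered > 0 and lam > 0:
            depths[:covered] = rng.poisson(lam, size=covered)

        counts = np.zeros((L, 4), dtype=np.int64)
        nz = np.flatnonzero(depths)
        if nz.size:
            base_idx = np.frombuffer(truth.encode(), dtype=np.uint8)
            lut = np.zeros(256, dtype=np.int64)
            for i, b in enumerate(b"ACGT"):
                lut[b] = i
            tidx = lut[base_idx[nz]]
            pvals = np.full((nz.size, 4), _ERROR_RATE / 3)
            pvals[np.arange(nz.size), tidx] = 1.0 - _ERROR_RATE
            counts[nz] = rng.multinomial(depths[nz], pvals)

        profiles[m.gene_id] = DepthProfile(m.gene_id, rid, depths)
        pileups[m.gene_id] = [
            PileupColumn(m.gene_id, int(p), {b: int(c) for b, c in zip("ACGT", counts[p])})
            for p in nz
        ]
        truth_cds[m.gene_id] = truth
        truth_tiers[m.gene_id] = (
            Tier.FIRST if m.role == "control" else expected_tier(scenario, cfg)
        )

    return SimulatedReadset(
        readset_id=rid,
        models=list(genes),
        profiles=profiles,
        pileups=pileups,
        truth_cds=truth_cds,
        truth_tiers=truth_tiers,
        control_depth=control_depth,
        seed=seed,
    )


def _random_cds(rng: np.random.Generator, length: int) -> str:
    """A random intact reading frame of the given length.

    ATG start, sense codons in the middle, one terminal stop. Lengths not
    a multiple of 3 (or < 6) fall back to a random ACGT sequence — such
    genes can never satisfy the frame check, which is fine for
    non-coding-length fixtures.
    """
    if length < 6 or length % 3 != 0:
        return "".join(rng.choice(list("ACGT"), size=length))
    n_mid = length // 3 - 2
    mid = rng.choice(_SENSE_CODONS, size=n_mid)
    stop = rng.choice(_STOPS)
    return "ATG" + "".join(mid) + stop


# ---------------------------------------------------------------------------
# canned study designs

def simulate_scenario_suite(
    seed: int = 0,
    gene_length: int = 600,
    control_depth: float = 40.0,
    cfg: ClassifierConfig = ClassifierConfig(),
) -> tuple[list[SimulatedReadset], dict[tuple[str, str], Tier]]:
    """Two readsets jointly covering all seven scenarios.

    A deep readset (control depth 40) carries one query gene per
    per-gene scenario; a shallow readset (control depth 8) carries a
    single absent gene, realising the LOW_COVERAGE_SET regime. Returns
    the readsets and the (readset, gene) → expected-tier truth map.
    """
    per_gene = [
        "PRESENT_SINGLE", "PRESENT_DUPLICATED", "PLASTID_INSERT",
        "PSEUDOGENE_PARTIAL", "NUCLEAR_RESIDUAL", "ABSENT",
    ]
    deep_queries = {f"q_{name.lower()}": gene_length for name in per_gene}
    deep_models = make_panel(deep_queries)
    deep_scen = {f"q_{n.lower()}": Scenario.default(n) for n in per_gene}
    deep = simulate_readset(
        deep_models, deep_scen, control_depth=control_depth, seed=seed,
        readset_id=f"deep{seed}", cfg=cfg,
    )

    shallow_models = make_panel({"q_low_coverage_set": gene_length})
    shallow_scen = {"q_low_coverage_set": Scenario.default("LOW_COVERAGE_SET")}
    shallow = simulate_readset(
        shallow_models, shallow_scen, control_depth=LOW_COVERAGE_CONTROL_DEPTH,
        seed=seed + 1, readset_id=f"shallow{seed}", cfg=cfg,
    )

    truth = {}
    for rs, scen in ((deep, deep_scen), (shallow, shallow_scen)):
        for gene, sc in scen.items():
            truth[(rs.readset_id, gene)] = expected_tier(sc, cfg)
    return [deep, shallow], truth


#: the 20-gene demonstration panel: 3 controls, 10 retained single-copy
#: genes, one duplicated region, one plastid insert, one decaying partial
#: pseudogene, three outright losses, one nuclear residual
EXAMPLE_SCENARIOS: dict[str, str] = {
    "cox1": "PRESENT_SINGLE", "cox2": "PRESENT_SINGLE", "cox3": "PRESENT_SINGLE",
    "cob": "PRESENT_SINGLE", "nad1": "PRESENT_SINGLE", "nad2": "PRESENT_SINGLE",
    "nad5": "PRESENT_SINGLE", "atp1": "PRESENT_SINGLE", "atp6": "PRESENT_SINGLE",
    "atp9": "PRESENT_SINGLE",
    "atp8": "PRESENT_DUPLICATED",
    "psaA_insert": "PLASTID_INSERT",
    "rpl2": "PSEUDOGENE_PARTIAL",
    "rps10": "ABSENT", "sdh3": "ABSENT", "sdh4": "ABSENT",
    "rps14": "NUCLEAR_RESIDUAL",
}


def example_readset(
    seed: int = 0,
    gene_length: int = 600,
    control_depth: float = 40.0,
    cfg: ClassifierConfig = ClassifierConfig(),
) -> SimulatedReadset:
    """The canned 20-gene readset used by the CLI and the worked example."""
    models = make_panel({g: gene_length for g in EXAMPLE_SCENARIOS})
    scenarios = {g: Scenario.default(n) for g, n in EXAMPLE_SCENARIOS.items()}
    return simulate_readset(
        models, scenarios, control_depth=control_depth, seed=seed,
        readset_id=f"example{seed}", cfg=cfg,
    )
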