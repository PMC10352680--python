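"""Synthetic expression, interactome and drug-target generators.

The generators plant known structure — differentially expressed genes with a
fixed log2 fold change, an approximately scale-free interactome carrying a
high-confidence hub module, and drugs targeting the hubs — so that every
downstream stage of the pipeline can be exercised and scored against ground
truth without any external download.

Hub-module anatomy
------------------
Besides the ``n_hubs`` designated hub genes (mutually connected, each wired
to well over a dozen planted DE genes at interaction scores above 900), the
module deliberately contains two families of *decoy* genes:

* **connectors** — low-degree genes adjacent to every hub, hence globally
  central (short paths to everything) but locally sparse;
* **spikes** — a dense clique hanging off one hub, hence locally
  high-degree but globally peripheral.

Distance- and neighbourhood-quality-driven centralities (radiality,
Laplacian, Katz, semi-local) rank connectors above spikes, while
local-degree-driven centralities (degree, MNC, edge-percolated component)
rank spikes above connectors.  Only the hubs score highly under *every*
algorithm, so recovering exactly the hubs genuinely requires the
multi-algorithm consensus rather than any single measure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .containers import CASE, CONTROL, ExpressionMatrix, InvalidConfigError

#: Minimum number of planted DE genes each hub is wired to at score > 900.
MIN_HUB_PARTNERS = 15

_N_CONNECTORS = 8
_N_SPIKES = 8

_ATC_NERVOUS = ("N01AB", "N02AA", "N03AX", "N04BC", "N05BA", "N06AB", "N07BC")
_ATC_OTHER = ("A02BC", "C07AB", "J01CA", "L01XA")

#: Drugs hitting exactly {4, 3, 2, 1} planted hub genes, mirroring the
#: bucket structure of the drug–key-gene network the pipeline reproduces.
DEFAULT_DRUG_BUCKETS: Mapping[int, int] = {4: 14, 3: 8, 2: 19, 1: 35}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the planted-structure simulation.

    Defaults reproduce the study design the pipeline targets: 10 case vs 10
    control samples, 1000 genes of which 100 are differentially expressed at
    |log2FC| = 1 with Gaussian noise of SD 0.5 on the log2 scale, and four
    hub genes embedded in the interactome at scores above 900.
    """

    n_genes: int = 1000
    n_samples_per_group: int = 10
    n_de_genes: int = 100
    planted_log2fc: float = 1.0
    noise_sd: float = 0.5
    n_hubs: int = 4
    hub_gene_fraction_de: float = 0.9
    interactome_score_range: tuple[int, int] = (400, 1000)
    n_drugs: int = 80
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_samples_per_group <= 0:
            raise InvalidConfigError("counts must be positive")
        if self.n_de_genes <= 0 or self.n_de_genes > self.n_genes:
            raise InvalidConfigError("need 0 < n_de_genes <= n_genes")
        if self.n_hubs < 0 or self.n_hubs > self.n_de_genes:
            raise InvalidConfigError("need 0 <= n_hubs <= n_de_genes")
        # noise_sd = 0 is the degenerate deterministic limit and is allowed
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be non-negative")
        if self.planted_log2fc <= 0:
            raise InvalidConfigError("planted_log2fc must be positive")
        if not 0.0 <= self.hub_gene_fraction_de <= 1.0:
            raise InvalidConfigError("hub_gene_fraction_de must lie in [0, 1]")
        lo, hi = self.interactome_score_range
        if not (0 <= lo <= hi <= 1000):
            raise InvalidConfigError("interactome_score_range must lie in [0, 1000]")
        if self.n_drugs < 0:
            raise InvalidConfigError("n_drugs must be non-negative")


@dataclass
class DEGroundTruth:
    """Planted truth serialized beside simulation outputs.

    ``log2fc`` maps every gene to its planted case-minus-control log2 fold
    change (0.0 for null genes); role lists partition the hub module.
    """

    gene_ids: list[str]
    log2fc: dict[str, float]
    de_genes: list[str]
    hubs: list[str]
    connectors: list[str] = field(default_factory=list)
    spikes: list[str] = field(default_factory=list)
    satellites: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "DEGroundTruth":
        return cls(**json.loads(text))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "DEGroundTruth":
        return cls.from_json(Path(path).read_text())


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _assign_roles(config: SimulationConfig, rng: np.random.Generator) -> DEGroundTruth:
    """Pick DE genes, choose fold-change signs, and carve out the hub module."""
    genes = _gene_ids(config.n_genes)
    de = sorted(rng.choice(config.n_genes, size=config.n_de_genes, replace=False))
    de_genes = [genes[i] for i in de]
    signs = rng.choice([-1.0, 1.0], size=config.n_de_genes)
    log2fc = {g: 0.0 for g in genes}
    for g, s in zip(de_genes, signs):
        log2fc[g] = float(s) * config.planted_log2fc

    truth = DEGroundTruth(
        gene_ids=genes, log2fc=log2fc, de_genes=de_genes, hubs=[]
    )
    if config.n_hubs == 0:
        return truth

    module_size = int(round(config.hub_gene_fraction_de * config.n_de_genes))
    module_size = max(module_size, config.n_hubs)
    pool = [str(g) for g in rng.permutation(de_genes)[:module_size]]
    truth.hubs = sorted(pool[: config.n_hubs])
    rest = pool[config.n_hubs:]
    n_conn = min(_N_CONNECTORS, len(rest))
    truth.connectors = sorted(rest[:n_conn])
    rest = rest[n_conn:]
    n_spk = min(_N_SPIKES, len(rest)) if config.n_hubs >= 1 else 0
    truth.spikes = sorted(rest[:n_spk])
    sats = rest[n_spk:]

    # satellites split among hubs with decreasing weights so hub degrees differ
    weights = np.arange(config.n_hubs, 0, -1, dtype=float)
    weights /= weights.sum()
    counts = np.floor(weights * len(sats)).astype(int)
    counts[0] += len(sats) - counts.sum()
    pos = 0
    for hub, c in zip(truth.hubs, counts):
        truth.satellites[hub] = sorted(sats[pos: pos + c])
        pos += c

    # hub wiring feasibility: every hub must reach MIN_HUB_PARTNERS DE genes
    for i, hub in enumerate(truth.hubs):
        partners = len(truth.satellites[hub]) + len(truth.connectors)
        partners += (config.n_hubs - 1)
        if hub == truth.hubs[-1]:
            partners += len(truth.spikes)
        if partners < MIN_HUB_PARTNERS:
            raise InvalidConfigError(
                f"hub wiring impossible: hub {hub} can reach only {partners} "
                f"planted DE genes (< {MIN_HUB_PARTNERS}); increase n_de_genes "
                "or hub_gene_fraction_de"
            )
    return truth


def simulate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, DEGroundTruth]:
    """Draw a log2-scale expression matrix with planted group differences.

    Every planted DE gene's case-group mean exceeds (or falls short of) its
    control-group mean by exactly the signed planted log2 fold change;
    null genes have identical group means.  I.i.d. Gaussian noise with
    ``config.noise_sd`` is added to every measurement.

    Returns
    -------
    (ExpressionMatrix, DEGroundTruth)
        The matrix and the planted-truth ledger (DE genes, signs, hub roles).
    """
    rng = np.random.default_rng(config.rng_seed)
    truth = _assign_roles(config, rng)
    n, m = config.n_genes, config.n_samples_per_group

    baseline = rng.normal(8.0, 1.5, size=n)
    delta = np.array([truth.log2fc[g] for g in truth.gene_ids])
    noise = rng.normal(0.0, config.noise_sd, size=(n, 2 * m)) if config.noise_sd > 0 \
        else np.zeros((n, 2 * m))

    ctrl_ids = [f"ctrl_{i + 1:02d}" for i in range(m)]
    case_ids = [f"case_{i + 1:02d}" for i in range(m)]
    values = np.empty((n, 2 * m))
    values[:, :m] = baseline[:, None] + noise[:, :m]
    values[:, m:] = (baseline + delta)[:, None] + noise[:, m:]

    df = pd.DataFrame(values, index=truth.gene_ids, columns=ctrl_ids + case_ids)
    groups = {s: CONTROL for s in ctrl_ids} | {s: CASE for s in case_ids}
    return ExpressionMatrix(values=df, groups=groups), truth


def _module_edges(
    truth: DEGroundTruth, rng: np.random.Generator
) -> list[tuple[str, str]]:
    edges: list[tuple[str, str]] = []
    hubs = truth.hubs
    for i, a in enumerate(hubs):
        for b in hubs[i + 1:]:
            edges.append((a, b))
    for c in truth.connectors:
        for h in hubs:
            edges.append((c, h))
    if truth.spikes:
        spike_hub = hubs[-1]
        for s in truth.spikes:
            edges.append((s, spike_hub))
        for i, a in enumerate(truth.spikes):
            for b in truth.spikes[i + 1:]:
                edges.append((a, b))
    for hub, sats in truth.satellites.items():
        for s in sats:
            edges.append((hub, s))
    return edges


def simulate_interactome(
    config: SimulationConfig, ground_truth: DEGroundTruth
) -> pd.DataFrame:
    """Generate a scored edge list with a planted high-confidence hub module.

    A preferential-attachment (Barabási–Albert) backbone over all genes
    provides the approximately scale-free bulk, with confidence scores drawn
    uniformly across ``config.interactome_score_range``; the hub-module edges
    are overlaid with scores in (900, 1000] so the module survives the
    standard score filter intact.

    Returns
    -------
    pandas.DataFrame
        Columns ``protein1``, ``protein2``, ``combined_score`` (int,
        0–1000); one row per unordered pair, ``protein1 < protein2``.
    """
    rng = np.random.default_rng(config.rng_seed + 1)
    genes = ground_truth.gene_ids
    m_attach = min(2, config.n_genes - 1)
    backbone = nx.barabasi_albert_graph(
        config.n_genes, m_attach, seed=int(rng.integers(2**31))
    )
    lo, hi = config.interactome_score_range
    scores: dict[tuple[str, str], int] = {}
    for u, v in backbone.edges():
        a, b = sorted((genes[u], genes[v]))
        scores[(a, b)] = int(rng.integers(lo, hi + 1))
    for u, v in _module_edges(ground_truth, rng):
        a, b = sorted((u, v))
        scores[(a, b)] = int(rng.integers(901, 1001))

    rows = sorted(scores.items())
    return pd.DataFrame(
        [(a, b, s) for (a, b), s in rows],
        columns=["protein1", "protein2", "combined_score"],
    )


def simulate_drug_targets(
    config: SimulationConfig,
    key_genes: Sequence[str],
    buckets: Mapping[int, int] = DEFAULT_DRUG_BUCKETS,
    other_genes: Sequence[str] = (),
    n_decoy_drugs: int = 4,
) -> pd.DataFrame:
    """Generate a drug→gene target table with fixed key-gene hit buckets.

    ``buckets`` maps a hit count to the number of nervous-system (ATC class
    N) drugs that target exactly that many of ``key_genes``.  ``n_decoy_drugs``
    additional non-N drugs also target key genes, exercising the ATC filter;
    remaining drugs up to ``config.n_drugs`` target only ``other_genes``
    (or nothing).

    Returns
    -------
    pandas.DataFrame
        Columns ``drug_id``, ``atc_code``, ``gene``; (drug, gene) pairs
        unique.
    """
    rng = np.random.default_rng(config.rng_seed + 2)
    key = sorted(set(key_genes))
    if config.n_drugs == 0:
        return pd.DataFrame(columns=["drug_id", "atc_code", "gene"])
    total = sum(buckets.values()) + n_decoy_drugs
    if total > config.n_drugs:
        raise InvalidConfigError(
            f"requested {total} drugs (buckets + decoys) but n_drugs={config.n_drugs}"
        )
    if buckets and not key:
        raise InvalidConfigError("key_genes is empty but buckets are requested")
    if buckets and max(buckets) > len(key):
        raise InvalidConfigError(
            f"bucket for {max(buckets)} hits exceeds |key_genes|={len(key)}"
        )

    rows: list[tuple[str, str, str]] = []
    drug_no = 0

    def next_drug(prefixes: tuple[str, ...]) -> tuple[str, str]:
        nonlocal drug_no
        drug_no += 1
        code = str(rng.choice(prefixes)) + f"{int(rng.integers(1, 100)):02d}"
        return f"D{drug_no:04d}", code

    for n_hit in sorted(buckets, reverse=True):
        for _ in range(buckets[n_hit]):
            drug, atc = next_drug(_ATC_NERVOUS)
            targets = rng.choice(key, size=n_hit, replace=False)
            rows.extend((drug, atc, str(g)) for g in sorted(targets))
    for _ in range(n_decoy_drugs):
        drug, atc = next_drug(_ATC_OTHER)
        n_hit = int(rng.integers(1, len(key) + 1))
        targets = rng.choice(key, size=n_hit, replace=False)
        rows.extend((drug, atc, str(g)) for g in sorted(targets))
    pool = [g for g in other_genes if g not in set(key)]
    while drug_no < config.n_drugs:
        drug, atc = next_drug(_ATC_NERVOUS)
        if pool:
            n_t = int(rng.integers(1, min(3, len(pool)) + 1))
            targets = rng.choice(pool, size=n_t, replace=False)
            rows.extend((drug, atc, str(g)) for g in sorted(targets))
        else:  # drug with no recorded targets: keep out of the table
            pass

    return pd.DataFrame(rows, columns=["drug_id", "atc_code", "gene"])
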