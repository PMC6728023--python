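"""The ensemble evaluation protocol.

For every organism set in an ensemble, nine distance matrices are computed
(three alignment-based: DENZS, D1ENZ, DRIBO; six network-based: DS1, DS2,
DNET1-DNET4), each is turned into a rescaled dendrogram, and every pair of
dendrograms is scored with the Robinson-Foulds metric — C(9,2) = 36
comparisons per set, plus one DRAND column per method obtained by averaging
that method's dendrogram against k random dendrograms.  Per-pair values are
then averaged over all sets of the ensemble, with the sample standard
deviation reported as uncertainty.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from itertools import combinations
from pathlib import Path

import numpy as np

from .dendro import Dendrogram, build_dendrogram, random_distance_matrix
from .io_formats import Dataset, EnsembleSpec, write_distance_tsv, write_newick
from .netdist import NETWORK_METHODS, network_distance_matrix
from .seqdist import GENE_METHODS, GapPenalty, distance_matrix_gene, load_matrix
from .treecmp import robinson_foulds

__all__ = [
    "METHODS",
    "RunConfig",
    "ComparisonTable",
    "child_rng",
    "build_all",
    "compare_set",
    "aggregate",
    "run_ensemble",
]

log = logging.getLogger(__name__)

#: the nine non-random construction methods, in reporting order
METHODS = ("DENZS", "D1ENZ", "DRIBO", "DS1", "DS2", "DNET1", "DNET2", "DNET3", "DNET4")
RANDOM_METHOD = "DRAND"

# stream offsets for child-seed spawning; methods occupy 0..8, random
# dendrograms 1000 + replicate
_RANDOM_STREAM_BASE = 1000


@dataclass
class RunConfig:
    """Resolved run parameters; defaults follow the reference protocol."""

    protein_matrix: str = "BLOSUM62"
    nucleotide_matrix: str = "NUC"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    damping: float = 0.85
    pagerank_tol: float = 1e-10
    n_random: int = 100
    methods: tuple[str, ...] = METHODS

    @property
    def gap(self) -> GapPenalty:
        return GapPenalty(open_cost=self.gap_open, extend_cost=self.gap_extend)


def child_rng(master_seed: int, *key: int) -> np.random.Generator:
    """Independent generator spawned from the master seed and a stable key.

    Keys identify (set index, stream), so adding a method or replicate never
    perturbs the randomness of the others.
    """
    return np.random.default_rng(np.random.SeedSequence(entropy=master_seed, spawn_key=key))


def build_all(
    org_set: list[str],
    dataset: Dataset,
    config: RunConfig,
    master_seed: int,
    set_index: int = 0,
) -> tuple[dict[str, Dendrogram], list[Dendrogram]]:
    """All method dendrograms plus the random baselines for one organism set.

    Raises with the method and set named if any method's preconditions fail
    (for example, an empty common-EC set for DENZS/D1ENZ).
    """
    orgs = sorted(org_set)
    dendros: dict[str, Dendrogram] = {}
    pmat = load_matrix(config.protein_matrix)
    nmat = load_matrix(config.nucleotide_matrix)
    gap = config.gap
    for mi, method in enumerate(config.methods):
        try:
            if method in GENE_METHODS:
                mat = nmat if method == "DRIBO" else pmat
                rng = child_rng(master_seed, set_index, mi)
                D = distance_matrix_gene(orgs, dataset, method, mat, gap, rng)
            elif method in NETWORK_METHODS:
                nets = []
                for org in orgs:
                    if org not in dataset.networks:
                        raise ValueError(f"no network for organism {org!r}")
                    nets.append(dataset.networks[org])
                D = network_distance_matrix(
                    nets, method, damping=config.damping, tol=config.pagerank_tol
                )
            else:
                raise ValueError(f"unknown method {method!r}")
            dendros[method] = build_dendrogram(D)
        except ValueError as exc:
            raise ValueError(f"method {method} failed on set {set_index}: {exc}") from exc
    randoms = [
        build_dendrogram(
            random_distance_matrix(orgs, child_rng(master_seed, set_index, _RANDOM_STREAM_BASE + r))
        )
        for r in range(config.n_random)
    ]
    return dendros, randoms


def compare_set(
    dendros: dict[str, Dendrogram],
    randoms: list[Dendrogram] | None = None,
) -> dict[tuple[str, str], float]:
    """Pairwise Robinson-Foulds values for one set.

    Returns one value per unordered method pair (C(m,2) of them) and, when
    random dendrograms are supplied, one ``(method, DRAND)`` entry per method
    holding the mean RF of that method's dendrogram against all randoms.
    """
    names = [m for m in METHODS if m in dendros] or sorted(dendros)
    out: dict[tuple[str, str], float] = {}
    for a, b in combinations(names, 2):
        out[(a, b)] = float(robinson_foulds(dendros[a], dendros[b]))
    if randoms:
        for a in names:
            vals = [robinson_foulds(dendros[a], r) for r in randoms]
            out[(a, RANDOM_METHOD)] = float(np.mean(vals))
    return out


@dataclass
class ComparisonTable:
    """Mean +/- sample std of the RF distance per method pair, across sets."""

    mean: dict[tuple[str, str], float]
    std: dict[tuple[str, str], float]
    n_sets: int
    methods: tuple[str, ...] = METHODS

    def columns(self) -> list[str]:
        cols = [m for m in self.methods]
        if any(RANDOM_METHOD in pair for pair in self.mean):
            cols.append(RANDOM_METHOD)
        return cols

    def to_tsv(self, path: str | Path) -> None:
        """Upper-triangular layout: each cell 'mean ± std'."""
        cols = self.columns()
        with open(Path(path), "w", encoding="utf-8") as fh:
            fh.write("DENDROGRAMS\t" + "\t".join(cols[1:]) + "\n")
            for i, row in enumerate(cols[:-1]):
                cells = []
                for col in cols[i + 1:]:
                    key = (row, col)
                    if key in self.mean:
                        cells.append(f"{self.mean[key]:.3f} ± {self.std[key]:.3f}")
                    else:
                        cells.append("")
                fh.write(row + "\t" + "\t".join(cells) + "\n")

    def to_long_tsv(self, path: str | Path) -> None:
        with open(Path(path), "w", encoding="utf-8") as fh:
            fh.write("method_a\tmethod_b\tmean_rf\tstd_rf\tn_sets\n")
            for (a, b), mu in sorted(self.mean.items()):
                fh.write(f"{a}\t{b}\t{mu:.6g}\t{self.std[(a, b)]:.6g}\t{self.n_sets}\n")


def aggregate(per_set: list[dict[tuple[str, str], float]]) -> ComparisonTable:
    """Mean and sample (n-1) standard deviation per pair across sets.

    With a single set the standard deviation is reported as 0 (logged).
    """
    if not per_set:
        raise ValueError("no per-set comparison results to aggregate")
    keys = sorted(per_set[0])
    for k, res in enumerate(per_set[1:], start=2):
        if sorted(res) != keys:
            raise ValueError(f"set {k} reports a different pair list")
    mean: dict[tuple[str, str], float] = {}
    std: dict[tuple[str, str], float] = {}
    n = len(per_set)
    if n == 1:
        log.warning("single set: standard deviations reported as 0")
    for key in keys:
        vals = np.array([res[key] for res in per_set])
        mean[key] = float(vals.mean())
        std[key] = float(vals.std(ddof=1)) if n > 1 else 0.0
    return ComparisonTable(mean=mean, std=std, n_sets=n)


def run_ensemble(
    spec: EnsembleSpec,
    dataset: Dataset,
    config: RunConfig,
    seed: int,
    out_dir: str | Path | None = None,
) -> ComparisonTable:
    """Full protocol over an ensemble; deterministic under (spec, config, seed).

    When ``out_dir`` is given, writes per-set dendrograms as Newick, per-set
    RF tables, the aggregate comparison tables and a JSON manifest.
    """
    results = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        (out / "trees").mkdir(parents=True, exist_ok=True)
        (out / "tables").mkdir(parents=True, exist_ok=True)
    for si, org_set in enumerate(spec.sets):
        dendros, randoms = build_all(org_set, dataset, config, seed, set_index=si)
        res = compare_set(dendros, randoms)
        results.append(res)
        log.info("set %d/%d: %d comparisons", si + 1, len(spec.sets), len(res))
        if out is not None:
            for method, d in dendros.items():
                write_newick(d, out / "trees" / f"set{si + 1}_{method}.nwk")
            with open(out / "tables" / f"set{si + 1}_rf.tsv", "w", encoding="utf-8") as fh:
                fh.write("method_a\tmethod_b\trf\n")
                for (a, b), v in sorted(res.items()):
                    fh.write(f"{a}\t{b}\t{v:.6g}\n")
    table = aggregate(results)
    if out is not None:
        table.to_tsv(out / "tables" / "comparison.tsv")
        table.to_long_tsv(out / "tables" / "comparison_long.tsv")
        manifest = {
            "tool": "metadendro",
            "seed": seed,
            "n_sets": len(spec.sets),
            "config": asdict(config),
        }
        manifest["config"]["methods"] = list(config.methods)
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2) + "\n", encoding="utf-8"
        )
    return table
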