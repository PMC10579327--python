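"""Synthetic input-bundle generator with planted ground truth.

Emits every table the pipeline reads — three ligase source lists, ligand
activity tables, bulk tumor/normal expression matrices, protein-staining
calls, normal and tumor single-cell count matrices, six PPI source
dialects, tractability lists, essentiality matrices, location, structure
and interface tables — together with a truth manifest recording every
derived quantity the pipeline is expected to reproduce (confidence, tier,
expression flags, PPI degrees, essentiality and location calls, structure
and interface counts, and the expected result sets of the preset queries).

Planting is margin-aware: High tissues receive a forced median well above
the classification boundary and Low tissues well below, so the planted
calls are guaranteed; boundary behavior is exercised separately through
:func:`make_boundary_fixtures`. Each table draws from its own random
stream derived from the master seed and the table name, so adding a table
never perturbs the others, and a given seed yields a byte-identical bundle.
"""
from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import yaml
from scipy import io as scipy_io
from scipy import sparse

from . import annotations as ann
from . import catalog as cat
from . import expression as expr
from . import ligandability as lig
from . import ppi as ppi_mod
from .errors import ConfigError
from .stats import round_half_up

VIOLATIONS = ("confidence", "ligand", "tcga", "gtex", "ppi")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic bundle.

    Defaults emulate a desk-scale atlas: 200 ligases against 1000 candidate
    targets, 10 tumor types and 10 normal tissues with 12 bulk samples
    each, 300 cells per normal tissue plus a 2000-cell tumor dataset.
    """

    n_ligases: int = 200
    n_targets: int = 1000
    n_tumor_types: int = 10
    n_normal_tissues: int = 10
    samples_per_tissue: int = 12
    cells_per_tissue: int = 300
    tumor_cells: int = 2000
    n_case1_passers: int = 5
    n_co_opted: int = 6
    n_clinical: int = 2
    seed: int = 0
    # noise parameters
    bulk_sd: float = 0.6
    high_median_range: tuple[float, float] = (5.0, 7.0)
    low_median_range: tuple[float, float] = (0.8, 3.4)
    sc_high_frac: float = 0.35
    sc_low_frac: float = 0.05
    sc_high_mean: float = 3.0
    sc_low_mean: float = 1.5

    def validate(self) -> None:
        positive = (
            self.n_ligases, self.n_targets, self.n_tumor_types,
            self.n_normal_tissues, self.samples_per_tissue,
            self.cells_per_tissue, self.tumor_cells,
        )
        if any(v <= 0 for v in positive):
            raise ConfigError("all bundle sizes must be positive")
        if not (0 <= self.n_case1_passers <= self.n_ligases):
            raise ConfigError("n_case1_passers must lie in [0, n_ligases]")
        if self.n_targets < 105:
            # the preset's PPI criterion is strict (>100 partners); planting
            # a passer or near-passer needs headroom in the target pool
            raise ConfigError("n_targets must be at least 105")
        if self.n_clinical > self.n_co_opted or self.n_co_opted > self.n_ligases:
            raise ConfigError("need n_clinical <= n_co_opted <= n_ligases")
        if self.low_median_range[1] > expr.BULK_HIGH_THRESHOLD - 0.5:
            raise ConfigError("Low bulk medians must sit >= 0.5 below the boundary")
        if self.high_median_range[0] < expr.BULK_HIGH_THRESHOLD + 0.5:
            raise ConfigError("High bulk medians must sit >= 0.5 above the boundary")


@dataclass
class PlantedLigase:
    """Self-consistent planted properties of one synthetic ligase."""

    symbol: str
    source_scores: dict[str, int]
    tier: str
    has_drug: bool
    has_chem: bool
    has_cova: bool
    tcga_high: list[str]
    hpa_high: list[str]
    gtex_high: list[str]
    tabula_high: list[str]
    ppi_degree: int
    essential_mean_crispr: float
    essential_mean_rnai: float
    location_class: str  # cytoplasm-only | nucleus-only | both | neither
    n_pdb: int
    in_afdb: bool
    n_interfaces: int
    case1: bool
    co_opted: bool = False
    clinical: bool = False

    @property
    def confidence(self) -> int:
        return sum(self.source_scores.values())

    def check(self, cfg: SimConfig) -> None:
        if not (1 <= self.confidence <= 6):
            raise ConfigError(f"{self.symbol}: confidence out of range")
        if self.tier == lig.TIER_DRUG and not self.has_drug:
            raise ConfigError(f"{self.symbol}: E3drug without drug evidence")
        if self.tier == lig.TIER_CHEM and (self.has_drug or not self.has_chem):
            raise ConfigError(f"{self.symbol}: inconsistent E3chem plan")
        if self.tier == lig.TIER_COVA and (self.has_drug or self.has_chem or not self.has_cova):
            raise ConfigError(f"{self.symbol}: inconsistent E3cova plan")
        if self.tier == lig.TIER_DARK and (self.has_drug or self.has_chem or self.has_cova):
            raise ConfigError(f"{self.symbol}: E3dark with ligand evidence")
        if self.case1:
            if self.confidence <= 3 or self.tier == lig.TIER_DARK:
                raise ConfigError(f"{self.symbol}: planted passer fails catalog/ligand")
            if not self.tcga_high or self.ppi_degree <= 100:
                raise ConfigError(f"{self.symbol}: planted passer fails expression/PPI")
            if len(self.gtex_high) / cfg.n_normal_tissues >= 0.30:
                raise ConfigError(f"{self.symbol}: planted passer fails GTEx fraction")


def _rng(seed: int, table: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), zlib.crc32(table.encode())])


# ------------------------------------------------------------------ planning

_SCORE_COMBOS: dict[int, list[dict[str, int]]] = {}
for _ge in (None, 1, 2):
    for _uh in (None, 1, 2):
        for _ub in (None, 1, 2):
            combo = {
                s: v
                for s, v in ((cat.GE, _ge), (cat.UBIHUB, _uh), (cat.UBIBROWSER, _ub))
                if v is not None
            }
            if combo:
                _SCORE_COMBOS.setdefault(sum(combo.values()), []).append(combo)


def _pick_scores(rng: np.random.Generator, confidence: int) -> dict[str, int]:
    options = _SCORE_COMBOS[confidence]
    return dict(options[rng.integers(len(options))])


def _pick_tier(rng: np.random.Generator, allow_dark: bool) -> tuple[str, bool, bool, bool]:
    tiers = [lig.TIER_DRUG, lig.TIER_CHEM, lig.TIER_COVA]
    if allow_dark:
        tiers.append(lig.TIER_DARK)
    tier = tiers[rng.integers(len(tiers))]
    if tier == lig.TIER_DRUG:
        return tier, True, bool(rng.integers(2)), bool(rng.integers(2))
    if tier == lig.TIER_CHEM:
        return tier, False, True, bool(rng.integers(2))
    if tier == lig.TIER_COVA:
        return tier, False, False, True
    return tier, False, False, False


def plan_ligases(cfg: SimConfig) -> list[PlantedLigase]:
    """Deterministically plan every ligase's properties from the config."""
    cfg.validate()
    rng = _rng(cfg.seed, "plan")
    symbols = [f"E3L{i + 1:03d}" for i in range(cfg.n_ligases)]
    tumor_types = [f"CANCER{i + 1:02d}" for i in range(cfg.n_tumor_types)]
    tissues = [f"TISSUE{i + 1:02d}" for i in range(cfg.n_normal_tissues)]
    passers = set(rng.choice(symbols, size=cfg.n_case1_passers, replace=False))
    max_gtex_pass = int(np.ceil(0.30 * cfg.n_normal_tissues)) - 1  # frac < 0.30, strict
    min_gtex_fail = max_gtex_pass + 1

    planted: list[PlantedLigase] = []
    non_passer_idx = 0
    for sym in symbols:
        is_passer = sym in passers
        violation = None
        if not is_passer:
            # first non-passer is the confidence-3 near-passer boundary plant
            violation = (
                "confidence3"
                if non_passer_idx == 0
                else VIOLATIONS[non_passer_idx % len(VIOLATIONS)]
            )
            non_passer_idx += 1

        if is_passer:
            confidence = int(rng.integers(4, 7))
        elif violation == "confidence3":
            confidence = 3
        elif violation == "confidence":
            confidence = int(rng.integers(1, 4))
        else:
            confidence = int(rng.integers(1, 7))

        if violation == "ligand":
            tier, has_drug, has_chem, has_cova = lig.TIER_DARK, False, False, False
        else:
            tier, has_drug, has_chem, has_cova = _pick_tier(
                rng, allow_dark=not is_passer and violation not in ("confidence3",)
            )
        if is_passer or violation == "confidence3":
            # passers and the near-passer must hold every other criterion
            tcga_n = int(rng.integers(1, max(2, cfg.n_tumor_types // 2)))
            gtex_n = int(rng.integers(0, max_gtex_pass + 1))
            degree = int(rng.integers(105, min(161, cfg.n_targets + 1)))
        else:
            tcga_n = 0 if violation == "tcga" else int(rng.integers(0, cfg.n_tumor_types + 1))
            gtex_n = (
                int(rng.integers(min_gtex_fail, cfg.n_normal_tissues + 1))
                if violation == "gtex"
                else int(rng.integers(0, cfg.n_normal_tissues + 1))
            )
            degree = (
                int(rng.integers(3, 101))
                if violation == "ppi"
                else int(rng.integers(2, min(141, cfg.n_targets)))
            )
        hpa_n = int(rng.integers(0, cfg.n_tumor_types + 1))
        tabula_n = int(rng.integers(0, cfg.n_normal_tissues + 1))
        essential_c = rng.random() < 0.15
        essential_r = rng.random() < 0.08
        loc_class = ["cytoplasm-only", "nucleus-only", "both", "neither"][
            rng.integers(4)
        ]
        n_pdb = int(rng.choice([0, 0, 0, 1, 2, 3, 5]))
        planted.append(
            PlantedLigase(
                symbol=sym,
                source_scores=_pick_scores(rng, confidence),
                tier=tier,
                has_drug=has_drug,
                has_chem=has_chem,
                has_cova=has_cova,
                tcga_high=sorted(rng.choice(tumor_types, size=tcga_n, replace=False)),
                hpa_high=sorted(rng.choice(tumor_types, size=hpa_n, replace=False)),
                gtex_high=sorted(rng.choice(tissues, size=gtex_n, replace=False)),
                tabula_high=sorted(rng.choice(tissues, size=tabula_n, replace=False)),
                ppi_degree=degree,
                essential_mean_crispr=float(
                    rng.uniform(0.62, 0.90) if essential_c else rng.uniform(0.08, 0.38)
                ),
                essential_mean_rnai=float(
                    rng.uniform(0.62, 0.90) if essential_r else rng.uniform(0.08, 0.38)
                ),
                location_class=loc_class,
                n_pdb=n_pdb,
                in_afdb=bool(rng.random() < 0.95),
                n_interfaces=int(rng.integers(0, 7)),
                case1=is_passer,
            )
        )
    # co-opted flags: prefer high-confidence ligases, as curated sets would
    by_conf = sorted(planted, key=lambda p: (-p.confidence, p.symbol))
    for i, p in enumerate(by_conf[: cfg.n_co_opted]):
        p.co_opted = True
        p.clinical = i < cfg.n_clinical
    for p in planted:
        p.check(cfg)
    return planted


def plant_case1_passers(cfg: SimConfig, k: int) -> SimConfig:
    """Return a config planting exactly ``k`` preset-passing ligases."""
    if not (0 <= k <= cfg.n_ligases):
        raise ConfigError(f"cannot plant {k} passers among {cfg.n_ligases} ligases")
    return replace(cfg, n_case1_passers=k)


# ------------------------------------------------------------------ emission helpers

def _force_median(rng, n: int, target: float, sd: float) -> np.ndarray:
    values = rng.normal(target, sd, size=n)
    values += target - np.median(values)
    return np.clip(values, 0.0, None).round(4)


def _exact_mean_positive(rng, n: int, target: float) -> np.ndarray:
    values = rng.exponential(1.0, size=n) + 0.5
    values *= target / values.mean()
    return values.round(4)


def _bulk_tables(cfg, planted, columns_of, high_of, rng):
    genes = [p.symbol for p in planted]
    tissues = sorted({t for p in planted for t in columns_of})
    samples = [f"{t}_S{j + 1:02d}" for t in tissues for j in range(cfg.samples_per_tissue)]
    matrix = np.zeros((len(genes), len(samples)))
    for gi, p in enumerate(planted):
        for ti, tissue in enumerate(tissues):
            lo, hi = (
                cfg.high_median_range if tissue in high_of(p) else cfg.low_median_range
            )
            target = rng.uniform(lo, hi)
            cols = slice(ti * cfg.samples_per_tissue, (ti + 1) * cfg.samples_per_tissue)
            matrix[gi, cols] = _force_median(rng, cfg.samples_per_tissue, target, cfg.bulk_sd)
    values = pd.DataFrame(matrix, index=genes, columns=samples)
    meta = pd.DataFrame(
        {"sample_id": samples, "tissue": [s.rsplit("_S", 1)[0] for s in samples]}
    )
    return values, meta


def _sc_matrix(cfg, planted, tissues, cells_per_tissue, high_of, rng, prefix):
    """Sparse cells x genes log-normalized matrix with planted High calls."""
    genes = [p.symbol for p in planted]
    cell_ids, cell_tissue = [], []
    for t in tissues:
        for j in range(cells_per_tissue):
            cell_ids.append(f"{prefix}_{t}_C{j + 1:04d}")
            cell_tissue.append(t)
    rows, cols, data = [], [], []
    for ti, tissue in enumerate(tissues):
        offset = ti * cells_per_tissue
        for gi, p in enumerate(planted):
            if tissue in high_of(p):
                frac, mean = cfg.sc_high_frac, cfg.sc_high_mean
            elif rng.random() < 0.5:
                frac, mean = cfg.sc_low_frac, cfg.sc_high_mean   # fraction fails
            else:
                frac, mean = cfg.sc_high_frac, cfg.sc_low_mean   # non-zero mean fails
            k = int(round(frac * cells_per_tissue))
            if k == 0:
                continue
            chosen = rng.choice(cells_per_tissue, size=k, replace=False)
            values = _exact_mean_positive(rng, k, mean)
            rows.extend(offset + chosen)
            cols.extend([gi] * k)
            data.extend(values)
    X = sparse.coo_matrix(
        (data, (rows, cols)), shape=(len(cell_ids), len(genes))
    ).tocsr()
    meta = pd.DataFrame({"cell_id": cell_ids, "tissue": cell_tissue})
    return X, meta, genes


# ------------------------------------------------------------------ generator

class _Truth:
    """Accumulates the manifest while tables are emitted."""

    def __init__(self):
        self.ligases: dict[str, dict] = {}
        self.queries: dict[str, list[str]] = {}
        self.ppi: dict = {}
        self.sc_composition: dict[str, dict] = {}
        self.target_query: dict = {}


def generate_bundle(cfg: SimConfig, out_dir) -> tuple[Path, dict]:
    """Write the full input bundle and its truth manifest.

    Returns the bundle directory and the manifest dict (also written as
    ``truth_manifest.json`` with per-file SHA-256 sums in
    ``checksums.txt``).
    """
    cfg.validate()
    planted = plan_ligases(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = _Truth()
    tumor_types = [f"CANCER{i + 1:02d}" for i in range(cfg.n_tumor_types)]
    tissues = [f"TISSUE{i + 1:02d}" for i in range(cfg.n_normal_tissues)]
    targets = [f"TGT{i + 1:04d}" for i in range(cfg.n_targets)]

    def write_tsv(name: str, frame: pd.DataFrame, **kwargs) -> None:
        frame.to_csv(out / name, sep="\t", index=False, **kwargs)

    # --- catalog sources -------------------------------------------------
    rng = _rng(cfg.seed, "catalog")
    aliased = planted[int(rng.integers(len(planted)))].symbol
    dup_ge = {p.symbol for p in planted if p.source_scores.get(cat.GE) == 2}
    dup_ge = set(sorted(dup_ge)[:2])  # two deliberate within-source duplicates
    ge_rows, ubihub_rows, ubibrowser_rows = [], [], []
    for p in planted:
        s = p.source_scores
        if cat.GE in s:
            ge_rows.append({"symbol": p.symbol, "lit_validated": s[cat.GE] == 2})
            if p.symbol in dup_ge:
                ge_rows.append({"symbol": p.symbol, "lit_validated": False})
        if cat.UBIHUB in s:
            text = (
                "E3 ubiquitin-protein ligase activity"
                if s[cat.UBIHUB] == 2
                else "ubiquitin-conjugation accessory factor"
            )
            name = f"ALIAS_{p.symbol}" if p.symbol == aliased else p.symbol
            ubihub_rows.append({"symbol": name, "function_text": text})
        if cat.UBIBROWSER in s:
            esi = int(rng.integers(6, 21)) if s[cat.UBIBROWSER] == 2 else int(rng.integers(0, 6))
            ubibrowser_rows.append({"symbol": p.symbol, "esi_count": esi})
    # decoy IAP-family member, dropped by the representative-IAP rule
    ge_rows.append({"symbol": "BIRC5", "lit_validated": True})
    write_tsv("ge.tsv", pd.DataFrame(ge_rows))
    write_tsv("ubihub.tsv", pd.DataFrame(ubihub_rows))
    write_tsv("ubibrowser_list.tsv", pd.DataFrame(ubibrowser_rows))
    write_tsv(
        "aliases.tsv",
        pd.DataFrame({"alias": [f"ALIAS_{aliased}"], "symbol": [aliased]}),
    )
    with open(out / "co_opted.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "co_opted": sorted(p.symbol for p in planted if p.co_opted),
                "clinical": sorted(p.symbol for p in planted if p.clinical),
            },
            fh,
        )

    # --- ligand evidence -------------------------------------------------
    rng = _rng(cfg.seed, "ligands")
    chembl_rows, drug_rows, cova_rows = [], [], []
    gid = 0
    for p in planted:
        keys: set[str] = set()
        if p.has_chem:
            for _ in range(int(rng.integers(1, 5))):
                gid += 1
                cid = f"CHEMBL{gid:05d}"
                chembl_rows.append(
                    {"ligand_id": cid, "chembl_id": cid, "smiles": "",
                     "target_symbol": p.symbol,
                     "pchembl": round(float(rng.uniform(5.0, 9.0)), 2)}
                )
                keys.add(cid)
            if rng.random() < 0.4:  # inactive record, must be filtered out
                gid += 1
                chembl_rows.append(
                    {"ligand_id": f"CHEMBL{gid:05d}", "chembl_id": f"CHEMBL{gid:05d}",
                     "smiles": "", "target_symbol": p.symbol,
                     "pchembl": round(float(rng.uniform(3.0, 4.9)), 2)}
                )
        if p.has_drug:
            shared = sorted(k for k in keys if k.startswith("CHEMBL"))
            for _ in range(int(rng.integers(1, 4))):
                gid += 1
                source = "DRUGBANK" if rng.random() < 0.5 else "DGIDB"
                drug_id = f"DB{gid:05d}"
                chembl_id = ""
                if shared and rng.random() < 0.3:
                    chembl_id = shared[0]  # cross-source duplicate of a ChEMBL ligand
                drug_rows.append(
                    {"drug_id": drug_id, "target_symbol": p.symbol,
                     "source": source, "chembl_id": chembl_id}
                )
                keys.add(chembl_id if chembl_id else f"{source}:{drug_id}")
        if p.has_cova:
            sites = rng.choice(np.arange(10, 500), size=int(rng.integers(1, 4)), replace=False)
            lines = ["HEK293T", "HCT116", "PC3"]
            for site in sites:
                cova_rows.append(
                    {"symbol": p.symbol, "cell_line": lines[int(rng.integers(3))],
                     "cysteine_site": f"C{int(site)}"}
                )
                keys.add(f"COVALENT:{p.symbol}:C{int(site)}")
            # same site observed again in another cell line: one ligand key
            cova_rows.append(
                {"symbol": p.symbol, "cell_line": "HEK293T",
                 "cysteine_site": f"C{int(sites[0])}"}
            )
        truth.ligases[p.symbol] = {"n_unique_ligands": len(keys)}
    drug_rows.append(
        {"drug_id": "DB99999", "target_symbol": "NOTALIGASE", "source": "DGIDB", "chembl_id": ""}
    )
    write_tsv("chembl_activities.tsv", pd.DataFrame(chembl_rows))
    write_tsv("drug_interactions.tsv", pd.DataFrame(drug_rows))
    write_tsv("covalent_hits.tsv", pd.DataFrame(cova_rows))

    # --- bulk expression -------------------------------------------------
    rng = _rng(cfg.seed, "tcga")
    tcga, tcga_meta = _bulk_tables(cfg, planted, tumor_types, lambda p: set(p.tcga_high), rng)
    tcga.insert(0, "symbol", tcga.index)
    write_tsv("tcga_expression.tsv", tcga, float_format="%.4f")
    write_tsv("tcga_samples.tsv", tcga_meta)
    rng = _rng(cfg.seed, "gtex")
    gtex, gtex_meta = _bulk_tables(cfg, planted, tissues, lambda p: set(p.gtex_high), rng)
    gtex.insert(0, "symbol", gtex.index)
    write_tsv("gtex_expression.tsv", gtex, float_format="%.4f")
    write_tsv("gtex_samples.tsv", gtex_meta)

    # --- protein staining ------------------------------------------------
    rng = _rng(cfg.seed, "hpa")
    n_samples = cfg.samples_per_tissue
    n_high = max(3, int(np.ceil(0.40 * n_samples)))  # well above the 20% rule
    hpa_rows = []
    for p in planted:
        for ct in tumor_types:
            k = n_high if ct in p.hpa_high else 1  # 1/12 sits well below 20%
            high_samples = set(rng.choice(n_samples, size=k, replace=False))
            for j in range(n_samples):
                if j in high_samples:
                    call = "high" if rng.random() < 0.5 else "medium"
                else:
                    call = "low" if rng.random() < 0.5 else "not_detected"
                hpa_rows.append(
                    {"symbol": p.symbol, "cancer_type": ct,
                     "sample_id": f"{ct}_P{j + 1:02d}", "staining_call": call}
                )
    write_tsv("hpa_staining.tsv", pd.DataFrame(hpa_rows))

    # --- single cell: normal tissues ------------------------------------
    rng = _rng(cfg.seed, "tabula")
    X, cells, genes = _sc_matrix(
        cfg, planted, tissues, cfg.cells_per_tissue,
        lambda p: set(p.tabula_high), rng, "TAB",
    )
    cell_types = ["T cell", "B cell", "macrophage", "epithelial cell", "endothelial cell"]
    cells["cell_type"] = [cell_types[int(i)] for i in rng.integers(0, len(cell_types), len(cells))]
    scipy_io.mmwrite(out / "tabula_counts.mtx", X.tocoo(), precision=4)
    write_tsv("tabula_genes.tsv", pd.DataFrame({"symbol": genes}))
    write_tsv("tabula_cells.tsv", cells)

    # --- single cell: tumor ----------------------------------------------
    rng = _rng(cfg.seed, "tumor_sc")
    n_mal = int(0.65 * cfg.tumor_cells)
    n_imm = int(0.25 * cfg.tumor_cells)
    n_oth = cfg.tumor_cells - n_mal - n_imm
    groups = ["malignant"] * n_mal + ["immune"] * n_imm + ["other"] * n_oth
    rows_sc, cols_sc, data_sc = [], [], []
    offsets = {"malignant": 0, "immune": n_mal, "other": n_mal + n_imm}
    sizes = {"malignant": n_mal, "immune": n_imm, "other": n_oth}
    for gi, p in enumerate(planted):
        counts = {}
        malignant_biased = rng.random() < 0.3
        for g in ("malignant", "immune", "other"):
            if malignant_biased:
                f = rng.uniform(0.4, 0.7) if g == "malignant" else rng.uniform(0.0, 0.1)
            else:
                f = rng.uniform(0.0, 0.3)
            k = int(round(f * sizes[g]))
            counts[g] = k
            if k:
                chosen = offsets[g] + rng.choice(sizes[g], size=k, replace=False)
                rows_sc.extend(chosen)
                cols_sc.extend([gi] * k)
                data_sc.extend(_exact_mean_positive(rng, k, 2.0))
        truth.sc_composition[p.symbol] = {
            g: {"n_expressing": counts[g], "n_cells": sizes[g]}
            for g in ("malignant", "immune", "other")
        }
    Xt = sparse.coo_matrix(
        (data_sc, (rows_sc, cols_sc)), shape=(cfg.tumor_cells, len(genes))
    )
    scipy_io.mmwrite(out / "tumor_sc_counts.mtx", Xt, precision=4)
    write_tsv("tumor_sc_genes.tsv", pd.DataFrame({"symbol": genes}))
    write_tsv(
        "tumor_sc_cells.tsv",
        pd.DataFrame(
            {
                "cell_id": [f"TUM_C{i + 1:05d}" for i in range(cfg.tumor_cells)],
                "tissue": tumor_types[0],
                "cell_type": groups,
                "malignant": [g == "malignant" for g in groups],
                "cell_group": groups,
            }
        ),
    )

    # --- PPI sources ------------------------------------------------------
    rng = _rng(cfg.seed, "ppi")
    source_rows: dict[str, list[dict]] = {s: [] for s in ppi_mod.PPI_SOURCES}
    edge_targets: dict[str, list[str]] = {}
    physical_methods = {
        ppi_mod.BIOGRID: ["Two hybrid", "Affinity chromatography technology", "Co-fractionation"],
        ppi_mod.INTACT: ["two hybrid", "affinity purification-mass spectrometry", "genetic interference"],
    }
    for p in planted:
        chosen = sorted(rng.choice(targets, size=p.ppi_degree, replace=False))
        edge_targets[p.symbol] = chosen
        for tgt in chosen:
            n_src = 1 + int(rng.random() < 0.3) + int(rng.random() < 0.1)
            for src in rng.choice(ppi_mod.PPI_SOURCES, size=n_src, replace=False):
                a, b = (p.symbol, tgt) if rng.random() < 0.8 else (tgt, p.symbol)
                if src == ppi_mod.BIOGRID:
                    source_rows[src].append(
                        {"symbol_a": a, "symbol_b": b, "organism_a": 9606, "organism_b": 9606,
                         "experimental_system": physical_methods[src][int(rng.integers(3))]}
                    )
                elif src == ppi_mod.INTACT:
                    source_rows[src].append(
                        {"protein_a": a, "protein_b": b, "taxid_a": 9606, "taxid_b": 9606,
                         "detection_method": physical_methods[src][int(rng.integers(3))]}
                    )
                elif src == ppi_mod.REACTOME:
                    source_rows[src].append(
                        {"interactor_a": a, "interactor_b": b, "species": "Homo sapiens"}
                    )
                elif src == ppi_mod.STRING:
                    source_rows[src].append(
                        {"protein1": a, "protein2": b, "species": 9606,
                         "combined_score": int(rng.integers(701, 1000))}
                    )
                elif src == ppi_mod.HURI:
                    source_rows[src].append(
                        {"symbol_a": a, "symbol_b": b, "assay": "yeast two-hybrid"}
                    )
                elif src == ppi_mod.UBIBROWSER_LIT:
                    source_rows[src].append(
                        {"e3": p.symbol, "substrate": tgt, "species": "Homo sapiens"}
                    )
                else:  # predicted ESI
                    source_rows[src].append(
                        {"e3": p.symbol, "substrate": tgt, "species": "Homo sapiens",
                         "confidence_score": round(float(rng.uniform(0.71, 0.99)), 3)}
                    )
    # decoy rows that every filter must drop; DECOY targets appear nowhere else
    source_rows[ppi_mod.STRING].append(
        {"protein1": planted[0].symbol, "protein2": "DECOY001", "species": 9606,
         "combined_score": 700}
    )
    source_rows[ppi_mod.STRING].append(
        {"protein1": planted[0].symbol, "protein2": "DECOY002", "species": 9606,
         "combined_score": 300}
    )
    source_rows[ppi_mod.UBIBROWSER_PRED].append(
        {"e3": planted[0].symbol, "substrate": "DECOY003", "species": "Homo sapiens",
         "confidence_score": 0.70}
    )
    source_rows[ppi_mod.BIOGRID].append(
        {"symbol_a": planted[0].symbol, "symbol_b": "DECOY004", "organism_a": 9606,
         "organism_b": 10090, "experimental_system": "Two hybrid"}
    )
    source_rows[ppi_mod.REACTOME].append(
        {"interactor_a": planted[0].symbol, "interactor_b": "DECOY005",
         "species": "Mus musculus"}
    )
    filenames = {
        ppi_mod.BIOGRID: "ppi_biogrid.tsv",
        ppi_mod.INTACT: "ppi_intact.tsv",
        ppi_mod.REACTOME: "ppi_reactome.tsv",
        ppi_mod.STRING: "ppi_string.tsv",
        ppi_mod.HURI: "ppi_huri.tsv",
        ppi_mod.UBIBROWSER_LIT: "esi_literature.tsv",
        ppi_mod.UBIBROWSER_PRED: "esi_predicted.tsv",
    }
    for src, name in filenames.items():
        write_tsv(name, pd.DataFrame(source_rows[src]))

    # tractability lists
    rng_t = _rng(cfg.seed, "tractability")
    protactable = sorted(rng_t.choice(targets, size=int(0.30 * cfg.n_targets), replace=False))
    mapd = sorted(rng_t.choice(targets, size=int(0.25 * cfg.n_targets), replace=False))
    write_tsv("protactable_genome.tsv", pd.DataFrame({"symbol": protactable}))
    write_tsv("mapd_targets.tsv", pd.DataFrame({"symbol": mapd}))

    # independent set-logic recomputation of the PPI summary statistics
    co_opted_syms = [p.symbol for p in planted if p.co_opted]
    e3_of_target: dict[str, set[str]] = {}
    for sym, tgts in edge_targets.items():
        for t in tgts:
            e3_of_target.setdefault(t, set()).add(sym)
    coopted_targets = {t for t, s in e3_of_target.items() if s & set(co_opted_syms)}
    all_targets_hit = set(e3_of_target)
    tractable_union = sorted(set(protactable) | set(mapd))
    med_coopted = float(
        np.median([len(e3_of_target.get(t, set()) & set(co_opted_syms)) for t in tractable_union])
    )
    med_all = float(np.median([len(e3_of_target.get(t, set())) for t in tractable_union]))
    truth.ppi = {
        "n_unique_edges": sum(len(t) for t in edge_targets.values()),
        "coopted_target_count": len(coopted_targets),
        "all_target_count": len(all_targets_hit),
        "expansion_pct": round_half_up(
            100.0 * (len(all_targets_hit) - len(coopted_targets)) / len(coopted_targets), 1
        )
        if coopted_targets
        else None,
        "tractability_overlap": len(set(protactable) & set(mapd)),
        "tractability_union": len(tractable_union),
        "median_e3_per_tractable_coopted": med_coopted,
        "median_e3_per_tractable_all": med_all,
    }

    # --- essentiality -----------------------------------------------------
    for screen, n_lines, n_lineages in (("crispr", 20, 4), ("rnai", 10, 2)):
        rng_e = _rng(cfg.seed, f"essentiality_{screen}")
        lines = [f"{screen.upper()}L{i + 1:02d}" for i in range(n_lines)]
        lineages = [f"LINEAGE{(i % n_lineages) + 1}" for i in range(n_lines)]
        matrix = np.zeros((len(planted), n_lines))
        for gi, p in enumerate(planted):
            m = getattr(p, f"essential_mean_{screen}")
            vals = rng_e.uniform(m - 0.08, m + 0.08, size=n_lines)
            vals += m - vals.mean()
            matrix[gi] = np.clip(vals, 0.0, 1.0).round(4)
        frame = pd.DataFrame(matrix, index=genes, columns=lines)
        frame.insert(0, "symbol", frame.index)
        write_tsv(f"essentiality_{screen}.tsv", frame, float_format="%.4f")
        write_tsv(f"{screen}_lines.tsv", pd.DataFrame({"line": lines, "lineage": lineages}))

    # --- locations, structures, interfaces --------------------------------
    rng_l = _rng(cfg.seed, "locations")
    loc_rows = []
    terms_of = {
        "cytoplasm-only": ["cytoplasm", "cytosol"],
        "nucleus-only": ["nucleus"],
        "both": ["cytoplasm", "nucleus"],
        "neither": ["mitochondrion", "plasma membrane"],
    }
    for p in planted:
        for term in terms_of[p.location_class]:
            src = ["GO", "COMPARTMENTS", "UNIPROT"][int(rng_l.integers(3))]
            score = round(float(rng_l.uniform(3.2, 5.0)), 2) if src == "COMPARTMENTS" else ""
            loc_rows.append({"symbol": p.symbol, "source": src, "term": term, "score": score})
        if p.location_class in ("cytoplasm-only", "neither") and rng_l.random() < 0.3:
            # low-confidence decoy that must be excluded by the score rule
            loc_rows.append(
                {"symbol": p.symbol, "source": "COMPARTMENTS", "term": "nucleus",
                 "score": round(float(rng_l.uniform(0.5, 3.0)), 2)}
            )
    write_tsv("locations.tsv", pd.DataFrame(loc_rows))

    rng_s = _rng(cfg.seed, "structures")
    pdb_rows, afdb_rows = [], []
    for p in planted:
        for i in range(p.n_pdb):
            pdb_rows.append({"symbol": p.symbol, "pdb_id": f"{int(rng_s.integers(1, 10))}{p.symbol[-3:]}{i}"})
        if p.in_afdb:
            afdb_rows.append({"symbol": p.symbol})
    write_tsv("structures_pdb.tsv", pd.DataFrame(pdb_rows))
    write_tsv("structures_afdb.tsv", pd.DataFrame(afdb_rows))

    rng_i = _rng(cfg.seed, "interfaces")
    iface_rows = []
    for p in planted:
        pool = edge_targets[p.symbol] or targets
        pairs: set[tuple[str, str]] = set()
        while len(pairs) < p.n_interfaces:
            partner = pool[int(rng_i.integers(len(pool)))]
            src = ann.INTERFACE_SOURCES[int(rng_i.integers(3))]
            pairs.add((partner, src))
        for partner, src in sorted(pairs):
            start = int(rng_i.integers(1, 400))
            end = start + int(rng_i.integers(5, 40))
            iface_rows.append(
                {"symbol": p.symbol, "partner": partner, "source": src,
                 "residues": f"{start}-{end}"}
            )
        if p.n_interfaces:  # duplicate record; set semantics keep the count
            iface_rows.append(dict(iface_rows[-1]))
    write_tsv("interfaces.tsv", pd.DataFrame(iface_rows))

    # --- manifest ---------------------------------------------------------
    for p in planted:
        n_tis = cfg.n_normal_tissues
        entry = truth.ligases[p.symbol]
        entry.update(
            {
                "confidence": p.confidence,
                "source_scores": dict(p.source_scores),
                "co_opted": p.co_opted,
                "clinical": p.clinical,
                "tier": p.tier,
                "has_drug": p.has_drug,
                "has_chem": p.has_chem,
                "has_cova": p.has_cova,
                "tcga_high": list(p.tcga_high),
                "hpa_high": list(p.hpa_high),
                "gtex_high": list(p.gtex_high),
                "tabula_high": list(p.tabula_high),
                "tumor_high_any_tcga": len(p.tcga_high) > 0,
                "tumor_high_any_hpa": len(p.hpa_high) > 0,
                "normal_low_majority_gtex": (n_tis - len(p.gtex_high)) / n_tis >= 0.70,
                "normal_low_majority_tabula": (n_tis - len(p.tabula_high)) / n_tis >= 0.70,
                "tumor_selective": (
                    len(p.tcga_high) > 0
                    and len(p.hpa_high) > 0
                    and (n_tis - len(p.gtex_high)) / n_tis >= 0.70
                    and (n_tis - len(p.tabula_high)) / n_tis >= 0.70
                ),
                "ppi_degree": p.ppi_degree,
                "essential_crispr": p.essential_mean_crispr > 0.5,
                "essential_rnai": p.essential_mean_rnai > 0.5,
                "in_cytoplasm": p.location_class in ("cytoplasm-only", "both"),
                "in_nucleus": p.location_class in ("nucleus-only", "both"),
                "favorable_location": p.location_class != "neither",
                "location_exclusivity": p.location_class
                if p.location_class != "neither"
                else "neither",
                "n_pdb": p.n_pdb,
                "afdb_available": p.n_pdb == 0 and p.in_afdb,
                "n_interfaces": p.n_interfaces,
                "case1": p.case1,
            }
        )
    truth.queries["case1"] = sorted(p.symbol for p in planted if p.case1)
    passer_syms = [p.symbol for p in planted if p.case1]
    if passer_syms:
        hits: dict[str, set[str]] = {}
        for sym in passer_syms:
            for t in edge_targets[sym]:
                hits.setdefault(t, set()).add(sym)
        best = max(sorted(hits), key=lambda t: len(hits[t]))
        truth.target_query = {"target": best, "expected": sorted(hits[best])}
    else:
        truth.target_query = {"target": targets[0], "expected": []}

    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(cfg).items()
        },
        "symbols": [p.symbol for p in planted],
        "ligases": truth.ligases,
        "queries": truth.queries,
        "target_query": truth.target_query,
        "ppi": truth.ppi,
        "sc_composition": truth.sc_composition,
        "tumor_sc_cancer_type": tumor_types[0],
    }
    with open(out / "truth_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    sums = []
    for path in sorted(out.iterdir()):
        if path.name == "checksums.txt" or not path.is_file():
            continue
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        sums.append(f"{digest}  {path.name}")
    (out / "checksums.txt").write_text("\n".join(sums) + "\n")
    return out, manifest


# ------------------------------------------------------------------ boundary fixtures

@dataclass(frozen=True)
class BoundaryCase:
    """One printed-threshold boundary probe: inputs plus the expected call."""

    rule: str
    value: float
    expected: object
    run: Callable[[], object]


def make_boundary_fixtures() -> list[BoundaryCase]:
    """Probes sitting exactly on (and just past) each printed threshold.

    Each case executes the corresponding pipeline operation on a minimal
    input and carries the expected strict/inclusive outcome.
    """
    thr = expr.derive_sc_thresholds()
    chembl = pd.DataFrame(
        {"ligand_id": ["a", "b"], "chembl_id": ["a", "b"], "smiles": ["", ""],
         "target_symbol": ["X", "X"], "pchembl": [5.0, 4.99]}
    )
    string_rows = pd.DataFrame(
        {"protein1": ["A", "A"], "protein2": ["B1", "B2"], "species": [9606, 9606],
         "combined_score": [700, 701]}
    )
    pred_rows = pd.DataFrame(
        {"e3": ["A", "A"], "substrate": ["B1", "B2"],
         "species": ["Homo sapiens", "Homo sapiens"],
         "confidence_score": [0.70, 0.71]}
    )
    comp = pd.DataFrame(
        {"symbol": ["X", "X"], "source": ["COMPARTMENTS", "COMPARTMENTS"],
         "term": ["nucleus", "cytoplasm"], "score": [3.0, 3.01]}
    )
    sc_frac_boundary = np.concatenate([np.full(51, 3.0), np.zeros(349)])   # 12.75%
    sc_frac_above = np.concatenate([np.full(52, 3.0), np.zeros(348)])      # 13.0%
    sc_mean_boundary = np.full(100, 2.325)
    sc_mean_above = np.full(100, 2.33)
    return [
        BoundaryCase("pchembl >= 5 (inclusive)", 5.0, ["a"],
                     lambda: lig.filter_active_chembl(chembl)["ligand_id"].tolist()),
        BoundaryCase("bulk median > 4 (strict)", 4.0, "Low", lambda: expr.classify_bulk(4.0)),
        BoundaryCase("bulk median > 4 (strict)", 4.01, "High", lambda: expr.classify_bulk(4.01)),
        BoundaryCase("hpa 20% (inclusive default)", 0.20, "High",
                     lambda: expr.classify_hpa(["medium"] * 2 + ["low"] * 8)),
        BoundaryCase("hpa 20% (strict variant)", 0.20, "Low",
                     lambda: expr.classify_hpa(["medium"] * 2 + ["low"] * 8, strict=True)),
        BoundaryCase("string > 700 (strict)", 700, ["B2"],
                     lambda: sorted(ppi_mod.load_source_edges(string_rows, ppi_mod.STRING)["b"])),
        BoundaryCase("esi confidence > 0.7 (strict)", 0.70, ["B2"],
                     lambda: sorted(
                         ppi_mod.load_source_edges(pred_rows, ppi_mod.UBIBROWSER_PRED)["b"]
                     )),
        BoundaryCase("essentiality mean > 0.5 (strict)", 0.5, False,
                     lambda: ann.essentiality_call({"l1": 0.5, "l2": 0.5})),
        BoundaryCase("essentiality mean > 0.5 (strict)", 0.51, True,
                     lambda: ann.essentiality_call({"l1": 0.51, "l2": 0.51})),
        BoundaryCase("compartments score > 3 (strict)", 3.0, ["cytoplasm"],
                     lambda: sorted(ann.filter_high_confidence(comp)["term"])),
        BoundaryCase("sc fraction > 12.75% (strict)", 12.75, "Low",
                     lambda: expr.classify_sc_tissue(sc_frac_boundary, thr)),
        BoundaryCase("sc fraction > 12.75% (strict)", 13.0, "High",
                     lambda: expr.classify_sc_tissue(sc_frac_above, thr)),
        BoundaryCase("sc non-zero mean > 2.325 (strict)", 2.325, "Low",
                     lambda: expr.classify_sc_tissue(sc_mean_boundary, thr)),
        BoundaryCase("sc non-zero mean > 2.325 (strict)", 2.33, "High",
                     lambda: expr.classify_sc_tissue(sc_mean_above, thr)),
        BoundaryCase("esi_count > 5 (strict)", 5, 1,
                     lambda: cat.score_source(
                         cat.SourceRecord("X", cat.UBIBROWSER, esi_count=5)
                     )),
        BoundaryCase("esi_count > 5 (strict)", 6, 2,
                     lambda: cat.score_source(
                         cat.SourceRecord("X", cat.UBIBROWSER, esi_count=6)
                     )),
    ]
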