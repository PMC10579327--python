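"""Bundle readers and end-to-end atlas construction.

A bundle is a directory of plain-text tables in the layout the synthetic
generator emits (and that real data-source exports can be massaged into):
three ligase source lists, ligand activity tables, bulk expression
matrices with sample metadata, protein staining calls, MTX single-cell
matrices with cell metadata, per-source PPI tables, tractability lists,
essentiality matrices and annotation tables. :func:`build_atlas` runs the
whole derivation — catalog assembly, ligandability tiering, High/Low
expression calls and selectivity flags, PPI merging, essentiality /
location / structure / interface summaries — and returns the
:class:`~e3prio.search.Atlas` the query engine operates on.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import anndata as ad
import pandas as pd
import yaml
from scipy import io as scipy_io
from scipy import sparse

from . import annotations as ann
from . import catalog as cat
from . import expression as expr
from . import ligandability as lig
from . import ppi as ppi_mod
from .errors import InputError
from .search import Atlas

logger = logging.getLogger(__name__)

PPI_FILES = {
    ppi_mod.BIOGRID: "ppi_biogrid.tsv",
    ppi_mod.INTACT: "ppi_intact.tsv",
    ppi_mod.REACTOME: "ppi_reactome.tsv",
    ppi_mod.STRING: "ppi_string.tsv",
    ppi_mod.HURI: "ppi_huri.tsv",
    ppi_mod.UBIBROWSER_LIT: "esi_literature.tsv",
    ppi_mod.UBIBROWSER_PRED: "esi_predicted.tsv",
}


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and variants applied during atlas construction."""

    bulk_high_threshold: float = expr.BULK_HIGH_THRESHOLD
    hpa_threshold_frac: float = expr.HPA_HIGH_FRAC
    hpa_strict: bool = False
    sc_ref_frac_pct: float = expr.SC_REFERENCE_FRAC_PCT
    sc_ref_mean: float = expr.SC_REFERENCE_MEAN
    sc_scale: float = expr.SC_SCALE
    majority_frac: float = expr.MAJORITY_FRAC


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_bulk(bundle: Path, prefix: str) -> tuple[pd.DataFrame, pd.Series]:
    values = pd.read_csv(bundle / f"{prefix}_expression.tsv", sep="\t", index_col="symbol")
    meta = _read_tsv(bundle / f"{prefix}_samples.tsv")
    return values, pd.Series(meta["tissue"].values, index=meta["sample_id"])


def read_sc(bundle: Path, prefix: str) -> ad.AnnData:
    """MTX + genes + cell-metadata triple as an AnnData (cells x genes)."""
    X = sparse.csr_matrix(scipy_io.mmread(bundle / f"{prefix}_counts.mtx"))
    genes = _read_tsv(bundle / f"{prefix}_genes.tsv")["symbol"].astype(str)
    cells = _read_tsv(bundle / f"{prefix}_cells.tsv")
    if cells["cell_type"].isna().any():
        raise InputError(f"{prefix}: cells with missing cell_type rejected at load")
    obs = cells.set_index("cell_id")
    obs.index = obs.index.astype(str)
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=genes.values))
    return adata


def load_edges(bundle: Path, alias_map=None) -> pd.DataFrame:
    raw = []
    for source, name in PPI_FILES.items():
        path = bundle / name
        if path.exists():
            raw.append(ppi_mod.load_source_edges(_read_tsv(path), source, alias_map=alias_map))
    if not raw:
        return ppi_mod.merge_edges(pd.DataFrame(columns=["a", "b", "source", "score", "physical"]))
    return ppi_mod.merge_edges(pd.concat(raw, ignore_index=True))


def build_atlas(bundle_dir, config: PipelineConfig | None = None) -> Atlas:
    """Run the full derivation over a bundle directory."""
    bundle = Path(bundle_dir)
    config = config or PipelineConfig()

    alias_path = bundle / "aliases.tsv"
    alias_map = cat.read_alias_map(alias_path) if alias_path.exists() else {}
    with open(bundle / "co_opted.yaml") as fh:
        co_cfg = yaml.safe_load(fh)
    co_opted = cat.CoOptedConfig(
        co_opted_symbols=frozenset(co_cfg.get("co_opted", ())),
        clinical_symbols=frozenset(co_cfg.get("clinical", ())),
    )
    catalog = cat.assemble_catalog(
        cat.read_source_table(bundle / "ge.tsv", cat.GE),
        cat.read_source_table(bundle / "ubihub.tsv", cat.UBIHUB),
        cat.read_source_table(bundle / "ubibrowser_list.tsv", cat.UBIBROWSER),
        co_opted=co_opted,
        alias_map=alias_map,
    )
    symbols = list(catalog.index)

    ligands = lig.summarize_ligandability(
        symbols,
        chembl=_read_tsv(bundle / "chembl_activities.tsv"),
        drugs=_read_tsv(bundle / "drug_interactions.tsv"),
        covalent=_read_tsv(bundle / "covalent_hits.tsv"),
    )

    tcga_values, tcga_meta = read_bulk(bundle, "tcga")
    gtex_values, gtex_meta = read_bulk(bundle, "gtex")
    tcga_calls = expr.bulk_calls(
        expr.bulk_tissue_medians(tcga_values, tcga_meta), config.bulk_high_threshold
    )
    gtex_calls = expr.bulk_calls(
        expr.bulk_tissue_medians(gtex_values, gtex_meta), config.bulk_high_threshold
    )
    hpa_calls = expr.hpa_call_table(
        _read_tsv(bundle / "hpa_staining.tsv"),
        threshold_frac=config.hpa_threshold_frac,
        strict=config.hpa_strict,
    )
    thresholds = expr.derive_sc_thresholds(
        config.sc_ref_frac_pct, config.sc_ref_mean, config.sc_scale
    )
    tabula = read_sc(bundle, "tabula")
    tabula_calls = expr.sc_call_table(tabula, thresholds)
    tumor_sc = read_sc(bundle, "tumor_sc") if (bundle / "tumor_sc_counts.mtx").exists() else None

    flags = expr.expression_flags(
        tcga_calls, hpa_calls, gtex_calls, tabula_calls,
        symbols=symbols, majority_frac=config.majority_frac,
    )

    edges = load_edges(bundle, alias_map=alias_map)

    essentiality = essentiality_rnai = None
    if (bundle / "essentiality_crispr.tsv").exists():
        crispr = pd.read_csv(bundle / "essentiality_crispr.tsv", sep="\t", index_col="symbol")
        essentiality = ann.essentiality_calls(crispr)
    if (bundle / "essentiality_rnai.tsv").exists():
        rnai = pd.read_csv(bundle / "essentiality_rnai.tsv", sep="\t", index_col="symbol")
        essentiality_rnai = ann.essentiality_calls(rnai)

    locations = None
    if (bundle / "locations.tsv").exists():
        loc_table = ann.filter_high_confidence(_read_tsv(bundle / "locations.tsv"))
        locations = ann.locate_all(loc_table, symbols)

    structures = None
    if (bundle / "structures_pdb.tsv").exists():
        pdb = _read_tsv(bundle / "structures_pdb.tsv")
        pdb_index = pdb.groupby("symbol")["pdb_id"].apply(set).to_dict() if not pdb.empty else {}
        afdb_path = bundle / "structures_afdb.tsv"
        afdb = set(_read_tsv(afdb_path)["symbol"]) if afdb_path.exists() else set()
        structures = ann.structure_table(symbols, pdb_index, afdb)

    interface_counts = None
    if (bundle / "interfaces.tsv").exists():
        index = ann.InterfaceIndex(_read_tsv(bundle / "interfaces.tsv"))
        interface_counts = index.counts(symbols)

    return Atlas(
        catalog=catalog,
        ligands=ligands,
        expression=flags,
        edges=edges,
        tcga_calls=tcga_calls,
        hpa_calls=hpa_calls,
        gtex_calls=gtex_calls,
        tabula_calls=tabula_calls,
        essentiality=essentiality,
        essentiality_rnai=essentiality_rnai,
        locations=locations,
        structures=structures,
        interface_counts=interface_counts,
        tumor_sc=tumor_sc,
    )


def write_derived_tables(atlas: Atlas, out_dir) -> None:
    """Emit the derived per-ligase tables as TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    atlas.catalog.to_csv(out / "catalog.tsv", sep="\t")
    atlas.ligands.to_csv(out / "ligandability.tsv", sep="\t")
    atlas.expression.to_csv(out / "expression_flags.tsv", sep="\t")
    ppi_mod.edges_to_table(atlas.edges).to_csv(out / "edges.tsv", sep="\t", index=False)
    for name, table in (
        ("essentiality_crispr_calls.tsv", atlas.essentiality),
        ("essentiality_rnai_calls.tsv", atlas.essentiality_rnai),
        ("locations_summary.tsv", atlas.locations),
        ("structures_summary.tsv", atlas.structures),
    ):
        if table is not None:
            table.to_csv(out / name, sep="\t")
    if atlas.interface_counts is not None:
        atlas.interface_counts.rename("n_interfaces").to_csv(
            out / "interface_counts.tsv", sep="\t", index_label="symbol"
        )
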