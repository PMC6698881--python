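"""Readers and writers for the plain-text interchange formats.

Cohorts are long-format TSV/CSV (two rows per family); polygenic weights a
3-column TSV; genotypes either a TSV dosage matrix (rows individuals) or a
VCF (DS dosages preferred, GT hard calls otherwise); GRMs are stored as
(id1, id2, value) triplets next to an id list. Simulation configs and run
manifests are YAML or JSON mirroring the dataclass field names.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .kinship import GRM
from .simulate import SimulationConfig

__all__ = [
    "read_cohort", "write_cohort", "read_weights", "read_genotype_matrix",
    "read_vcf", "write_grm", "read_grm", "load_simulation_config",
    "RunManifest", "load_manifest", "config_hash",
]


def _sep(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_cohort(path) -> pd.DataFrame:
    """Long-format cohort table; requires family_id and member columns."""
    df = pd.read_csv(path, sep=_sep(path))
    for col in ("family_id", "member"):
        if col not in df.columns:
            raise ValueError(f"cohort file lacks required column '{col}'")
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep=_sep(path), index=False)


def read_weights(path) -> pd.DataFrame:
    """Weights TSV with header: variant_id, effect_allele, weight."""
    df = pd.read_csv(path, sep="\t")
    need = {"variant_id", "effect_allele", "weight"}
    if not need.issubset(df.columns):
        raise ValueError(f"weights file needs header columns {sorted(need)}")
    if df["variant_id"].duplicated().any():
        raise ValueError("duplicate variant ids in weights file")
    if not np.isfinite(df["weight"].to_numpy(dtype=float)).all():
        raise ValueError("non-finite weights")
    return df


def read_genotype_matrix(path) -> pd.DataFrame:
    """Dosage matrix TSV: first column individual id, remaining variants."""
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    G = df.to_numpy(dtype=float)
    if G.size and (np.nanmin(G) < 0 or np.nanmax(G) > 2):
        raise ValueError("dosages must lie in [0, 2]")
    return df


def read_vcf(path):
    """Read a VCF into (dosage DataFrame, allele DataFrame).

    Dosages count the ALT allele, taken from the DS FORMAT field when
    present and otherwise from GT hard calls. The allele frame has columns
    variant_id, counted_allele, other_allele for allele matching during
    scoring. Requires the optional cyvcf2 dependency.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("VCF reading requires cyvcf2") from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols, ids, alleles = [], [], []
    for var in vcf:
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        ds = var.format("DS")
        if ds is not None:
            dose = np.asarray(ds, dtype=float).ravel()[: len(samples)]
        else:
            gt = np.asarray(var.genotype.array())[:, :2]
            dose = (gt > 0).sum(axis=1).astype(float)
            dose[(gt < 0).any(axis=1)] = np.nan
        ids.append(vid)
        cols.append(dose)
        alleles.append({"variant_id": vid, "counted_allele": var.ALT[0],
                       "other_allele": var.REF})
    geno = pd.DataFrame(np.column_stack(cols) if cols else np.empty((len(samples), 0)),
                        index=samples, columns=ids)
    return geno, pd.DataFrame(alleles, columns=["variant_id", "counted_allele",
                                                "other_allele"])


def write_grm(grm: GRM, prefix) -> None:
    """Write <prefix>.grm.tsv triplets and <prefix>.grm_ids.tsv."""
    prefix = str(prefix)
    n = len(grm.ids)
    iu = np.triu_indices(n)
    pd.DataFrame({
        "id1": [grm.ids[i] for i in iu[0]],
        "id2": [grm.ids[j] for j in iu[1]],
        "value": grm.matrix[iu],
    }).to_csv(prefix + ".grm.tsv", sep="\t", index=False)
    pd.DataFrame({"iid": grm.ids, "n_variants": grm.n_variants}) \
        .to_csv(prefix + ".grm_ids.tsv", sep="\t", index=False)


def read_grm(prefix) -> GRM:
    prefix = str(prefix)
    ids_df = pd.read_csv(prefix + ".grm_ids.tsv", sep="\t")
    ids = ids_df["iid"].tolist()
    n_variants = int(ids_df["n_variants"].iloc[0]) if len(ids_df) else 0
    pos = {v: i for i, v in enumerate(ids)}
    A = np.zeros((len(ids), len(ids)))
    trip = pd.read_csv(prefix + ".grm.tsv", sep="\t")
    i = trip["id1"].map(pos).to_numpy()
    j = trip["id2"].map(pos).to_numpy()
    A[i, j] = trip["value"].to_numpy()
    A[j, i] = trip["value"].to_numpy()
    return GRM(ids, A, n_variants)


def _load_structured(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def load_simulation_config(path) -> SimulationConfig:
    """YAML/JSON file whose keys mirror SimulationConfig field names."""
    d = _load_structured(path)
    if not isinstance(d, dict):
        raise ValueError("config file must contain a mapping")
    return SimulationConfig.from_dict(d)


def config_hash(obj) -> str:
    """Stable short hash of a config-like mapping, for provenance records."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    s = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(s.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Declarative description of a model grid run.

    ``covariate_sets`` maps a set name to covariate columns; the unadjusted
    model is the empty list. Every outcome x predictor x covariate-set cell
    is fitted and bootstrapped, and FDR correction is applied across all
    within/between coefficient p-values of the run as one hypothesis family.
    """

    cohort: str
    outcomes: list
    predictors: list
    covariate_sets: dict = field(default_factory=lambda: {"none": []})
    n_boot: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self):
        if not self.outcomes or not self.predictors:
            raise ValueError("manifest needs at least one outcome and predictor")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_boot < 0:
            raise ValueError("n_boot must be >= 0")


def load_manifest(path) -> RunManifest:
    d = _load_structured(path)
    known = {f.name for f in dataclasses.fields(RunManifest)}
    extra = set(d) - known
    if extra:
        raise ValueError(f"unknown manifest fields: {sorted(extra)}")
    missing = {"cohort", "outcomes", "predictors"} - set(d)
    if missing:
        raise ValueError(f"manifest missing required fields: {sorted(missing)}")
    return RunManifest(**d)
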