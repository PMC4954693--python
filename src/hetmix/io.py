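"""Data ingestion, QC, normalization and results serialization.

Expression matrices are genes x samples tables of Ct or Et values in
tabular text; non-detects are empty cells or the string "ND" (internally a
NaN in Et space, a linear value of exactly 0 once a per-gene Dataset is
built).  Per-sample metadata declares the pool size k, the condition and
optionally the plate.  Utilities implement the Ct -> Et = 40 - Ct
conversion, the sample QC filter (drop samples detecting < 10% of assayed
genes) and plate-median normalization against a reference spike-in.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import Dataset

__all__ = [
    "RawMatrix",
    "RunConfig",
    "read_matrix",
    "ct_to_et",
    "qc_filter_samples",
    "plate_normalize",
    "dataset_from_matrix",
    "write_dataset",
    "read_dataset",
    "load_config",
]

NONDETECT_STRINGS = ["", "ND", "NA", "nan"]
REQUIRED_META = ("k", "condition")


@dataclass
class RawMatrix:
    """Genes x samples expression table with per-sample metadata.

    values: DataFrame indexed by gene, one column per sample; NaN encodes a
    non-detect.  units is "Ct" or "Et".  meta is indexed by sample id and
    must carry columns k and condition (plate optional).
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    units: str = "Et"
    spike_genes: tuple = ()

    def __post_init__(self) -> None:
        if self.units not in ("Ct", "Et"):
            raise ValueError("units must be 'Ct' or 'Et'")
        missing = [c for c in REQUIRED_META if c not in self.meta.columns]
        if missing:
            raise ValueError(f"metadata missing required columns: {missing}")
        unknown = [s for s in self.values.columns if s not in self.meta.index]
        if unknown:
            raise ValueError(f"samples without metadata: {unknown[:5]}")

    @property
    def genes(self) -> list:
        return list(self.values.index)

    @property
    def samples(self) -> list:
        return list(self.values.columns)


def read_matrix(
    values_path,
    meta_path,
    units: str = "Et",
    spike_genes: tuple = (),
    sep: str | None = None,
) -> RawMatrix:
    """Read a genes x samples matrix and its sample metadata from CSV/TSV."""
    def _read(path):
        s = sep or ("\t" if str(path).endswith((".tsv", ".txt")) else ",")
        return pd.read_csv(
            path, sep=s, index_col=0,
            na_values=NONDETECT_STRINGS, keep_default_na=False,
        )

    values = _read(values_path).astype(float)
    meta = _read(meta_path)
    meta["k"] = meta["k"].astype(int)
    return RawMatrix(values, meta, units=units, spike_genes=tuple(spike_genes))


def ct_to_et(raw: RawMatrix, clamp_negative: bool = True) -> RawMatrix:
    """Convert Ct to Et = 40 - Ct; non-detects stay non-detects.

    Ct above 40 yields negative Et (amplification past the cycle ceiling):
    warned about, and clamped to 0 unless ``clamp_negative`` is False.
    """
    if raw.units != "Ct":
        raise ValueError("matrix is not in Ct units")
    et = 40.0 - raw.values
    n_neg = int((et < 0).sum().sum())
    if n_neg:
        warnings.warn(
            f"{n_neg} measurements had Ct > 40 (negative Et)"
            + ("; clamped to 0" if clamp_negative else ""),
            RuntimeWarning,
        )
        if clamp_negative:
            et = et.clip(lower=0.0)
    return RawMatrix(et, raw.meta, units="Et", spike_genes=raw.spike_genes)


def qc_filter_samples(
    raw: RawMatrix, min_detected_fraction: float = 0.10
) -> tuple[RawMatrix, dict]:
    """Drop samples detecting fewer than ``min_detected_fraction`` of the
    assayed genes; returns the filtered matrix and a report of dropped ids."""
    if raw.values.shape[0] < 1:
        raise ValueError("matrix has no genes")
    frac = raw.values.notna().mean(axis=0)
    keep = frac >= min_detected_fraction
    dropped = [s for s in raw.samples if not keep[s]]
    if not keep.any():
        raise ValueError("QC filter dropped every sample")
    filtered = RawMatrix(
        raw.values.loc[:, keep.index[keep]],
        raw.meta.loc[keep.index[keep]],
        units=raw.units,
        spike_genes=raw.spike_genes,
    )
    report = {
        "dropped_samples": dropped,
        "detected_fraction": {s: float(frac[s]) for s in raw.samples},
        "threshold": min_detected_fraction,
    }
    return filtered, report


def plate_normalize(raw: RawMatrix, reference_spike: str = "ERCC-0003") -> RawMatrix:
    """Equalize the per-plate medians of a reference spike-in.

    All detected Et values on a plate are shifted by (global reference median
    - plate median of the spike), where the global reference is the median of
    the per-plate spike medians; after shifting, the spike's per-plate
    medians coincide.  Non-detects are untouched; plates where the spike is
    entirely undetected are flagged and left unshifted.
    """
    if raw.units != "Et":
        raise ValueError("plate normalization expects Et units")
    if reference_spike not in raw.values.index:
        raise ValueError(f"reference spike {reference_spike!r} not in matrix")
    if "plate" not in raw.meta.columns:
        raise ValueError("metadata has no plate column")
    spike = raw.values.loc[reference_spike]
    plates = raw.meta["plate"]
    plate_medians = {}
    for plate in plates.unique():
        cols = plates.index[plates == plate]
        vals = spike[cols].dropna()
        plate_medians[plate] = float(vals.median()) if len(vals) else np.nan
    finite = [v for v in plate_medians.values() if np.isfinite(v)]
    if not finite:
        raise ValueError("reference spike undetected on every plate")
    target = float(np.median(finite))
    out = raw.values.copy()
    for plate, med in plate_medians.items():
        cols = plates.index[plates == plate]
        if not np.isfinite(med):
            warnings.warn(
                f"plate {plate!r}: reference spike undetected; left unshifted",
                RuntimeWarning,
            )
            continue
        out.loc[:, cols] = out.loc[:, cols] + (target - med)
    return RawMatrix(out, raw.meta, units="Et", spike_genes=raw.spike_genes)


def dataset_from_matrix(raw: RawMatrix, gene: str) -> Dataset:
    """Build one gene's Dataset (linear scale, 0 = non-detect)."""
    if raw.units != "Et":
        raise ValueError("convert to Et units first (ct_to_et)")
    if gene not in raw.values.index:
        raise ValueError(f"gene {gene!r} not in matrix")
    et = raw.values.loc[gene]
    values = np.where(et.notna(), np.exp2(et.fillna(0.0)), 0.0)
    meta = raw.meta.loc[raw.values.columns]
    plate = meta["plate"].to_numpy() if "plate" in meta.columns else None
    return Dataset(
        gene,
        values,
        meta["k"].to_numpy(),
        meta["condition"].to_numpy(),
        plate,
    )


# ---------------------------------------------------------------------------
# Dataset round-trip (long format)
# ---------------------------------------------------------------------------

def write_dataset(data: Dataset, path, sidecar: dict | None = None) -> None:
    """Write a Dataset as long-format CSV (Et column empty for non-detects);
    an optional sidecar JSON records provenance (scenario spec, seed)."""
    path = Path(path)
    with np.errstate(divide="ignore"):
        et = np.log2(data.values)
    df = pd.DataFrame(
        {
            "gene": data.gene_id,
            "sample_id": [f"s{i}" for i in range(len(data))],
            "k": data.k,
            "condition": data.condition,
            "Et": [f"{v:.17g}" if np.isfinite(v) else "" for v in et],
            "plate": data.plate if data.plate is not None else "",
        }
    )
    df.to_csv(path, index=False)
    if sidecar is not None:
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2, default=str))


def read_dataset(path) -> Dataset:
    """Read a long-format Dataset CSV written by ``write_dataset``."""
    df = pd.read_csv(path, na_values=NONDETECT_STRINGS, keep_default_na=False)
    et = pd.to_numeric(df["Et"], errors="coerce")
    values = np.where(et.notna(), np.exp2(et.fillna(0.0)), 0.0)
    plate = None
    if "plate" in df.columns and df["plate"].astype(str).str.len().gt(0).any():
        plate = df["plate"].to_numpy()
    gene = str(df["gene"].iloc[0]) if len(df) else "unknown"
    return Dataset(gene, values, df["k"].to_numpy(), df["condition"].to_numpy(), plate)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated configuration for a CLI run."""

    mode: str = "SCKC"  # SC | KC | SCKC
    seed: int = 0
    alpha: float = 0.05
    out_dir: str = "results"
    adapt_max_iters: int = 400_000
    burnin_iters: int = 20_000
    sample_iters: int = 200_000
    thin: int = 1
    assessment: str = "default"  # default | concat | ppp
    n_ppc_draws: int = 100
    p_min: float = 0.1
    fraction_threshold: float = 0.75
    sigma_cap: float = 5.0
    min_on_cells: int = 5

    def __post_init__(self) -> None:
        if self.mode not in ("SC", "KC", "SCKC"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.assessment not in ("default", "concat", "ppp"):
            raise ValueError(f"unknown assessment {self.assessment!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def mcmc_config(self, seed: int | None = None):
        from .mcmc import MCMCConfig

        return MCMCConfig(
            adapt_max_iters=self.adapt_max_iters,
            burnin_iters=self.burnin_iters,
            sample_iters=self.sample_iters,
            thin=self.thin,
            seed=self.seed if seed is None else seed,
        )


def load_config(path) -> RunConfig:
    """Load a RunConfig from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(payload, dict):
        raise ValueError("config must be a mapping")
    return RunConfig(**payload)
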