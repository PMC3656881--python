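"""File formats, model serialization, and the end-to-end pipeline.

All tabular I/O is tab-separated UTF-8 with a header row and ``.`` decimals;
sequences travel as FASTA.  Trained models serialize to a versioned JSON
container that round-trips decision values losslessly.  Pipeline runs write
a manifest recording input digests, the global seed and the package
version, so identical configurations reproduce byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import __version__
from .compilation import InteractionRecord, compile_datasets
from .evaluate import SelectionProtocol, select_model
from .peptides import Peptide, PeptideError
from .rebalance import RebalanceConfig, rebalance
from .scan import ScanConfig, ScanResult, scan
from .svm import SVMModel, train

INTERACTION_COLUMNS = ["domain_id", "peptide", "kd_nM", "label", "source"]


class TableFormatError(ValueError):
    """Raised when a TSV input is malformed beyond the error budget."""


def read_fasta(path: str | Path) -> Dict[str, str]:
    """Protein sequences keyed by record id."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(proteome: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(proteome):
            fh.write(f">{pid}\n{proteome[pid]}\n")


def read_interactions(
    path: str | Path, error_budget: int = 10
) -> List[InteractionRecord]:
    """Parse an interaction table (TSV: domain_id, peptide, kd_nM, label, source).

    Missing values are empty fields; a row must carry at least one of kd_nM
    or label.  Malformed rows are reported with their 1-based line number;
    more than ``error_budget`` bad rows aborts the read.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in INTERACTION_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required columns {missing}")
    records: List[InteractionRecord] = []
    errors: List[str] = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            kd = float(row["kd_nM"]) if row["kd_nM"].strip() else None
            label = int(float(row["label"])) if row["label"].strip() else None
            records.append(
                InteractionRecord(
                    domain_id=row["domain_id"].strip(),
                    peptide=Peptide(row["peptide"].strip()),
                    kd_nM=kd,
                    label=label,
                    source=row["source"].strip(),
                )
            )
        except (ValueError, PeptideError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        if len(errors) > error_budget:
            raise TableFormatError(
                f"{path}: {len(errors)} malformed rows (budget {error_budget}); first: {errors[0]}"
            )
        warnings.warn(f"{path}: skipped {len(errors)} malformed rows: {errors}", stacklevel=2)
    return records


def write_interactions(records: Sequence[InteractionRecord], path: str | Path) -> None:
    rows = [
        (
            r.domain_id,
            r.peptide.residues,
            "" if r.kd_nM is None else r.kd_nM,
            "" if r.label is None else r.label,
            r.source,
        )
        for r in records
    ]
    pd.DataFrame(rows, columns=INTERACTION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_phosphosites(path: str | Path) -> Set[Tuple[str, int]]:
    """TSV with columns (protein_id, site); site is 1-based."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "site": int})
    return {(r.protein_id, int(r.site)) for r in df.itertuples()}


def read_localization(path: str | Path) -> Dict[str, Set[str]]:
    """TSV with one (protein_id, term) row per annotation."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: Dict[str, Set[str]] = {}
    for r in df.itertuples():
        out.setdefault(r.protein_id, set()).add(r.term)
    return out


def save_model(model: SVMModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh)


def load_model(path: str | Path) -> SVMModel:
    with open(path) as fh:
        return SVMModel.from_dict(json.load(fh))


def write_predictions(result: ScanResult, path: str | Path) -> None:
    pd.DataFrame(
        result.as_rows(),
        columns=["domain_id", "protein_id", "site", "window", "score", "rank"],
    ).to_csv(path, sep="\t", index=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# --------------------------------------------------------------------------
# Pipeline configuration and runner


_KNOWN_KEYS = {
    "interactions",
    "primary_source",
    "min_positives",
    "scheme",
    "seed",
    "outdir",
    "rebalance",
    "grid",
    "protocol",
    "scan",
}
_KNOWN_REBALANCE = {"batch_fraction", "max_iterations"}
_KNOWN_GRID = {"degrees", "costs", "coef0"}
_KNOWN_PROTOCOL = {"outer", "n_outer_folds", "n_repeats", "n_inner_folds"}
_KNOWN_SCAN = {"proteome", "sites", "localization", "domain_proteins", "top_k", "promiscuity_threshold"}


@dataclass
class PipelineConfig:
    """Validated end-to-end pipeline configuration."""

    interactions: str
    outdir: str
    primary_source: Optional[str] = None
    min_positives: int = 40
    scheme: str = "full20"
    seed: int = 0
    rebalance: dict = field(default_factory=dict)
    grid: dict = field(default_factory=dict)
    protocol: dict = field(default_factory=dict)
    scan: Optional[dict] = None

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        for key, allowed in (
            ("rebalance", _KNOWN_REBALANCE),
            ("grid", _KNOWN_GRID),
            ("protocol", _KNOWN_PROTOCOL),
            ("scan", _KNOWN_SCAN),
        ):
            sub = raw.get(key) or {}
            bad = set(sub) - allowed
            if bad:
                raise ValueError(f"unknown keys under {key!r}: {sorted(bad)}")
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """compile -> rebalance -> select/train -> evaluate -> (optional) scan.

    Writes per-domain models, an evaluation report, a compilation report and
    a manifest into ``config.outdir``; returns the manifest dict.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = {"interactions": Path(config.interactions)}
    if config.scan:
        for k in ("proteome", "sites", "localization"):
            if config.scan.get(k):
                inputs[k] = Path(config.scan[k])

    records = read_interactions(inputs["interactions"])
    datasets, comp_report = compile_datasets(
        records, primary_source=config.primary_source, min_positives=config.min_positives
    )
    (outdir / "compilation_report.json").write_text(
        json.dumps(comp_report.to_dict(), indent=2, sort_keys=True)
    )

    reb_cfg = RebalanceConfig(seed=config.seed, **config.rebalance)
    grid = config.grid
    degrees = tuple(grid.get("degrees", (1, 2, 3)))
    costs = tuple(grid.get("costs", (0.01, 0.1, 1.0, 10.0, 100.0)))
    coef0 = float(grid.get("coef0", 1.0))
    protocol = SelectionProtocol(seed=config.seed, **config.protocol)

    models: Dict[str, SVMModel] = {}
    eval_rows = []
    for domain_id, ds in sorted(datasets.items()):
        X, y, X_pool = ds.encoded(config.scheme)
        Xp, Xn = X[y == 1], X[y == -1]
        result = rebalance(Xp, Xn, X_pool, config=reb_cfg)
        Xb = np.vstack([result.X_pos, result.X_neg])
        yb = np.concatenate([np.ones(len(result.X_pos)), -np.ones(len(result.X_neg))])
        modal, report, _ = select_model(
            Xb, yb, degrees=degrees, costs=costs, protocol=protocol, coef0=coef0
        )
        model = train(result.X_pos, result.X_neg, modal, seed=config.seed, scheme=config.scheme)
        models[domain_id] = model
        save_model(model, outdir / f"model_{domain_id}.json")
        summary = report.summary()
        eval_rows.append(
            {
                "domain_id": domain_id,
                "degree": modal.degree,
                "C": modal.C,
                "n_pos": ds.n_pos,
                "n_neg": ds.n_neg,
                "rebalance_iterations": result.n_iterations,
                **{k: (np.nan if v is None else round(v, 4)) for k, v in summary.items()},
            }
        )
    pd.DataFrame(eval_rows).to_csv(outdir / "evaluation.tsv", sep="\t", index=False)

    if config.scan:
        proteome = read_fasta(inputs["proteome"])
        scan_cfg = ScanConfig(
            models=models,
            phosphosites=read_phosphosites(inputs["sites"]),
            localization=read_localization(inputs["localization"]),
            domain_proteins=config.scan.get("domain_proteins", {}),
            top_k=int(config.scan.get("top_k", 50)),
            promiscuity_threshold=int(config.scan.get("promiscuity_threshold", 40)),
            scheme=config.scheme,
        )
        write_predictions(scan(proteome, scan_cfg), outdir / "predictions.tsv")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "inputs": {k: _sha256(p) for k, p in inputs.items()},
        "n_domains": len(models),
        "stages": ["compile", "rebalance", "select", "evaluate"] + (["scan"] if config.scan else []),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
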