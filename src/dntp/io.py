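"""File formats, pipeline configuration, and the end-to-end driver.

Formats are plain text throughout: expression as genes x samples TSV,
clinical as CSV, gene sets as GMT, signatures and reports as JSON.
Readers validate and reject rather than coerce; error messages carry
locations.  Treatment is coded 0 = NCHT, 1 = NHT everywhere; the string
labels are accepted at the file boundary only.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["read_expression", "write_expression", "read_clinical",
           "write_clinical", "PipelineConfig", "run_pipeline"]

logger = logging.getLogger("dntp")

_TREATMENT_ALIASES = {"0": 0, "1": 1, "NCHT": 0, "NHT": 1}


class ParseError(ValueError):
    pass


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples TSV (first column gene ids, header samples)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty expression file") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ParseError(f"{path}: no genes or no samples")
    dup = df.index[df.index.duplicated()].unique()
    if len(dup):
        raise ParseError(f"{path}: duplicate gene ids: {', '.join(map(str, dup[:5]))}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: non-numeric expression values") from exc
    if not np.all(np.isfinite(values)):
        r, c = np.argwhere(~np.isfinite(values))[0]
        raise ParseError(f"{path}: non-finite value at gene {df.index[r]!r}, "
                         f"sample {df.columns[c]!r}")
    if (values < 0).any():
        r, c = np.argwhere(values < 0)[0]
        raise ParseError(f"{path}: negative expression at gene {df.index[r]!r} "
                         f"(log2(TPM+1) must be >= 0)")
    return df.astype(float)


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


REQUIRED_CLINICAL = ("sample_id", "treatment", "time_months", "event")


def read_clinical(path) -> pd.DataFrame:
    """Read and validate a clinical CSV.

    Required columns: sample_id, treatment in {0,1,NCHT,NHT},
    time_months > 0, event in {0,1}.  Optional covariate columns pass
    through unchanged.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty clinical file") from exc
    missing = [c for c in REQUIRED_CLINICAL if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns: {', '.join(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"{path}: duplicate sample_id {dup!r}")
    treat = df["treatment"].astype(str).str.strip().map(_TREATMENT_ALIASES)
    if treat.isna().any():
        row = int(df.index[treat.isna()][0]) + 2  # header is line 1
        raise ParseError(f"{path}:{row}: treatment must be 0/1 or NCHT/NHT")
    df = df.copy()
    df["treatment"] = treat.astype(int)
    times = pd.to_numeric(df["time_months"], errors="coerce")
    if times.isna().any() or (times <= 0).any():
        row = int(df.index[times.isna() | (times <= 0)][0]) + 2
        raise ParseError(f"{path}:{row}: time_months must be a positive number")
    df["time_months"] = times.astype(float)
    if not df["event"].isin((0, 1)).all():
        row = int(df.index[~df["event"].isin((0, 1))][0]) + 2
        raise ParseError(f"{path}:{row}: event must be 0 or 1")
    df["event"] = df["event"].astype(int)
    return df


def write_clinical(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# pipeline driver

@dataclasses.dataclass
class PipelineConfig:
    """Configuration for the end-to-end run.

    With ``expression``/``clinical`` unset, a synthetic cohort is generated
    first with ``simulate`` options (a mapping of SyntheticConfig fields).
    """

    out_dir: str = "dntp_out"
    expression: str | None = None
    clinical: str | None = None
    alpha: float = 0.05
    min_expr_fraction: float = 0.2
    min_group_fraction: float = 0.2
    seed: int = 0
    simulate: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParseError(f"{path}: unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """simulate (optional) -> screen -> signature -> score -> scan-cutoff ->
    evaluate -> cohort table, writing every intermediate plus a manifest.

    Reruns with the same config and seed are bit-identical apart from the
    manifest timestamp field (which is omitted for exactly that reason:
    the manifest records content hashes, seed and versions only).
    """
    from . import __version__
    from .screen import InteractionScreen
    from .signature import build_signature, scan_cutoff, score_samples
    from .simulate import SyntheticConfig, generate_cohort
    from .subgroups import evaluate_subgroups, unstratified_comparison
    from .tables import build_cohort_table

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "input"
    try:
        if config.expression and config.clinical:
            expression = read_expression(config.expression)
            clinical = read_clinical(config.clinical)
        else:
            stage = "simulate"
            logger.info("[simulate] generating synthetic cohort")
            sim_cfg = SyntheticConfig(**{**config.simulate, "seed": config.seed})
            cohort = generate_cohort(sim_cfg)
            expression, clinical = cohort.expression, cohort.clinical
            write_expression(expression, out / "expression.tsv")
            write_clinical(clinical, out / "clinical.csv")

        stage = "screen"
        logger.info("[screen] fitting per-gene interaction models")
        screen = InteractionScreen(expression, clinical, alpha=config.alpha,
                                   min_expr_fraction=config.min_expr_fraction)
        results = screen.fit()
        results.to_tsv(out / "screen.tsv")

        stage = "build-signature"
        sig = build_signature(results, alpha=config.alpha)

        stage = "score"
        scores = score_samples(expression, sig)
        scores.rename_axis("sample_id").to_csv(out / "scores.tsv", sep="\t")

        stage = "scan-cutoff"
        logger.info("[scan-cutoff] scanning %d patients", len(scores))
        scan = scan_cutoff(scores, clinical,
                           min_group_fraction=config.min_group_fraction)
        sig = dataclasses.replace(sig, cutoff=scan.cutoff)
        sig.to_json(out / "signature.json")
        scan.diagnostics.to_csv(out / "cutoff_scan.tsv", sep="\t", index=False)

        stage = "evaluate"
        report = evaluate_subgroups(scores, clinical, scan.cutoff)
        overall = unstratified_comparison(clinical)
        payload = report.to_dict()
        payload["unstratified"] = {
            "logrank_p": overall.logrank_p, "hr": overall.hr,
            "hr_ci": overall.hr_ci, "median_per_arm": overall.median_per_arm}
        (out / "report.json").write_text(json.dumps(payload, indent=2) + "\n")

        stage = "table1"
        table1 = build_cohort_table(
            clinical.assign(arm=clinical["treatment"].map({0: "NCHT", 1: "NHT"})),
            "arm", categorical=[c for c in ("psa_cat", "gleason_cat", "t_stage",
                                            "n_stage") if c in clinical.columns],
            continuous=[c for c in ("age",) if c in clinical.columns])
        table1.to_csv(out / "table1.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "version": __version__,
        "outputs": {p.name: _sha256(p) for p in sorted(out.iterdir())
                    if p.is_file() and p.name != "manifest.json"},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
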