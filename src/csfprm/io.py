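"""Table readers/writers and pipeline configuration.

All tables are plain CSV. Output files carry a one-line ``#`` header comment
recording the tool version, a hash of the configuration, and the seed, so
any result file can be traced back to the run that produced it. Missing
values are written as empty fields.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io as _io
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .quantify import REQUIRED_TRANSITION_COLUMNS


class TransitionReportError(ValueError):
    """Fatal structural problem with a transition report."""


@dataclass
class PipelineConfig:
    """Configuration for the end-to-end pipeline.

    With ``simulate = True`` (default) the input tables are generated by the
    synthetic study generator; otherwise ``transitions``/``metadata``/
    ``library`` must point at CSV files.
    """

    seed: int = 0
    out_dir: str | None = None
    simulate: bool = True
    transitions: str | None = None
    metadata: str | None = None
    library: str | None = None
    discovery_log2fc: str | None = None
    reference_peptides: list[str] = field(default_factory=list)
    cv_threshold: float = 30.0
    fdr_alpha: float = 0.05
    alpha: float = 0.05
    ratio_threshold: float = 4.6
    folds: int = 5
    platform: str = "Luminex"
    per_batch_gis: bool = True
    sqrt_dotp: bool = True
    compute_dotp: bool = True

    def __post_init__(self) -> None:
        for name in ("cv_threshold", "ratio_threshold", "fdr_alpha", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not self.simulate:
            for name in ("transitions", "metadata"):
                path = getattr(self, name)
                if path is None:
                    raise ValueError(f"{name} file required when simulate=false")
                if not Path(path).exists():
                    raise FileNotFoundError(f"{name} file not found: {path}")

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> PipelineConfig:
    """Load a TOML config file; unknown keys are rejected."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    return PipelineConfig(**data)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_transition_report(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a long-format transition report CSV.

    Returns ``(records, rejected)``: well-typed rows, and rows dropped for a
    non-numeric or negative area (with a reason column). A missing required
    column is fatal and names the column.
    """
    frame = _read_csv(path)
    missing = [c for c in REQUIRED_TRANSITION_COLUMNS if c not in frame.columns]
    if missing:
        raise TransitionReportError(
            f"missing required column(s): {', '.join(missing)}")
    area = pd.to_numeric(frame["area"], errors="coerce")
    bad_numeric = area.isna() & frame["area"].notna()
    bad_negative = area < 0
    bad = bad_numeric | bad_negative | frame["area"].isna()
    rejected = frame[bad].copy()
    if len(rejected):
        reasons = pd.Series("missing area", index=rejected.index)
        reasons[bad_numeric[bad]] = "non-numeric area"
        reasons[bad_negative.reindex(rejected.index, fill_value=False)] = \
            "negative area"
        rejected["reason"] = reasons
    records = frame[~bad].copy()
    records["area"] = area[~bad]
    return records, rejected


def read_metadata(path: str | Path) -> pd.DataFrame:
    frame = _read_csv(path)
    if "sample_id" not in frame.columns or "group" not in frame.columns:
        raise TransitionReportError("metadata needs sample_id and group columns")
    return frame


def read_spectral_library(path: str | Path) -> pd.DataFrame:
    frame = _read_csv(path)
    need = {"peptide", "fragment_ion", "rel_intensity"}
    missing = need - set(frame.columns)
    if missing:
        raise TransitionReportError(
            f"library missing column(s): {', '.join(sorted(missing))}")
    return frame


def read_discovery_log2fc(path: str | Path) -> pd.Series:
    frame = _read_csv(path)
    if not {"protein", "log2fc"} <= set(frame.columns):
        raise TransitionReportError("discovery table needs protein, log2fc")
    return frame.set_index("protein")["log2fc"]


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_table(frame: pd.DataFrame, path: str | Path, config_hash: str = "-",
                seed: int | None = None, index: bool = True,
                float_format: str = "%.6f") -> None:
    """Write a CSV with a provenance header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    frame.to_csv(buf, index=index, float_format=float_format)
    header = (f"# csfprm v{__version__} | config_hash={config_hash} | "
              f"seed={seed if seed is not None else '-'}\n")
    path.write_text(header + buf.getvalue())
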