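"""Construction of labeled training sets from bicistronic-assay tables,
plus a synthetic fixture generator with the same schema.

The filtering pipeline retains native (non-synthetic) screen categories,
then rows passing both quality filters (splicing score strictly greater
than -2.5 AND promoter activity strictly less than 0.2), and finally
labels rows IRES when activity is strictly above 600 — all inequalities
strict, so boundary rows are excluded/nonIRES.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .kmer import BASES
from .sequence_io import RnaSequence

NATIVE_CATEGORIES = frozenset(
    {
        "CDS_screen",
        "Genome_Wide_Sceen_Elements",
        "High_Priority_Genes_Blocks",
        "High_Priority_Viruses_Blocks",
        "Human_5UTR_Screen",
        "IRESite_blocks",
        "Viral_5UTR_Screen",
        "rRNA_Matching_5UTRs",
    }
)

LABEL_IRES = "IRES"
LABEL_NONIRES = "nonIRES"

# default column mapping for external deposits whose layout is not fixed
DEFAULT_SCHEMA: Mapping[str, str] = {
    "id": "id",
    "sequence": "sequence",
    "category": "category",
    "ires_activity": "ires_activity",
    "splicing_score": "splicing_score",
    "promoter_activity": "promoter_activity",
}


@dataclass(frozen=True)
class AssayRecord:
    """One bicistronic-assay row: sequence, category, and activity scores."""

    id: str
    sequence: RnaSequence
    category: str
    ires_activity: float
    splicing_score: float
    promoter_activity: float
    label: str | None = None


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds and category whitelist; all inequalities strict."""

    allowed_categories: frozenset = NATIVE_CATEGORIES
    splicing_min: float = -2.5
    promoter_max: float = 0.2
    activity_threshold: float = 600.0

    def __post_init__(self):
        if not self.allowed_categories:
            raise ConfigError("allowed_categories must be non-empty")
        for v in (self.splicing_min, self.promoter_max, self.activity_threshold):
            if not np.isfinite(v):
                raise ConfigError("thresholds must be finite")


def filter_native(
    records: Sequence[AssayRecord], cfg: FilterConfig | None = None
) -> list[AssayRecord]:
    """Keep records whose category is whitelisted, preserving order."""
    cfg = cfg or FilterConfig()
    return [r for r in records if r.category in cfg.allowed_categories]


def apply_quality_filters(
    records: Sequence[AssayRecord], cfg: FilterConfig | None = None
) -> list[AssayRecord]:
    """Keep records with splicing > splicing_min and promoter < promoter_max."""
    cfg = cfg or FilterConfig()
    bad = [
        r.id
        for r in records
        if not (np.isfinite(r.splicing_score) and np.isfinite(r.promoter_activity))
    ]
    if bad:
        raise ValidationError("records with missing quality scores", ids=bad)
    return [
        r
        for r in records
        if r.splicing_score > cfg.splicing_min
        and r.promoter_activity < cfg.promoter_max
    ]


def assign_labels(
    records: Sequence[AssayRecord], cfg: FilterConfig | None = None
) -> list[AssayRecord]:
    """Label IRES iff activity is strictly above the threshold."""
    cfg = cfg or FilterConfig()
    bad = [r.id for r in records if not np.isfinite(r.ires_activity)]
    if bad:
        raise ValidationError("records with missing IRES activity", ids=bad)
    return [
        replace(
            r,
            label=LABEL_IRES
            if r.ires_activity > cfg.activity_threshold
            else LABEL_NONIRES,
        )
        for r in records
    ]


def class_counts(records: Iterable[AssayRecord]) -> tuple[int, int]:
    """(#IRES, #nonIRES) among labeled records."""
    pos = neg = 0
    for r in records:
        if r.label == LABEL_IRES:
            pos += 1
        elif r.label == LABEL_NONIRES:
            neg += 1
    return pos, neg


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------


def read_assay_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    sep: str = "\t",
) -> list[AssayRecord]:
    """Read an assay table (TSV/CSV with header) into AssayRecords.

    ``schema`` maps canonical field names (see DEFAULT_SCHEMA keys) to the
    file's actual column names, so externally deposited layouts can be
    adapted without code changes.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in schema.values() if c not in df.columns]
    if missing:
        raise ValidationError(f"assay table lacks columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        row = row._asdict()
        out.append(
            AssayRecord(
                id=str(row[schema["id"]]),
                sequence=RnaSequence(
                    str(row[schema["id"]]),
                    str(row[schema["sequence"]]).upper().replace("T", "U"),
                ),
                category=str(row[schema["category"]]),
                ires_activity=float(row[schema["ires_activity"]]),
                splicing_score=float(row[schema["splicing_score"]]),
                promoter_activity=float(row[schema["promoter_activity"]]),
            )
        )
    return out


def write_assay_table(
    records: Sequence[AssayRecord], path: str | Path, sep: str = "\t"
) -> None:
    """Write records (and labels, if assigned) as a delimited table."""
    df = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "sequence": [r.sequence.residues for r in records],
            "category": [r.category for r in records],
            "ires_activity": [r.ires_activity for r in records],
            "splicing_score": [r.splicing_score for r in records],
            "promoter_activity": [r.promoter_activity for r in records],
            "label": [r.label or "" for r in records],
        }
    )
    df.to_csv(path, sep=sep, index=False)


def read_schema_file(path: str | Path) -> dict[str, str]:
    """Parse a plain ``key = value`` column-mapping file."""
    mapping: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"bad schema line: {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in DEFAULT_SCHEMA:
            raise ConfigError(f"unknown schema field {key!r}")
        mapping[key] = value
    return mapping


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SignalConfig:
    """Generating distributions for the synthetic assay fixture.

    Negatives draw bases i.i.d. from ``neg_base_freqs``; positives from
    ``pos_base_freqs`` (U-enriched by default, mimicking the pyrimidine/U
    bias of active elements). ``hairpin`` optionally plants a
    stem-loop (GC stem) in positives so structure features separate too.
    """

    pos_base_freqs: tuple[float, float, float, float] = (0.20, 0.22, 0.20, 0.38)
    neg_base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    hairpin: bool = False
    hairpin_stem: int = 8
    hairpin_loop: int = 4
    pos_activity_range: tuple[float, float] = (601.0, 50000.0)
    neg_activity_range: tuple[float, float] = (206.0, 600.0)
    fail_fraction: float = 0.0  # fraction of rows failing quality filters

    def __post_init__(self):
        for freqs in (self.pos_base_freqs, self.neg_base_freqs):
            if len(freqs) != 4 or abs(sum(freqs) - 1.0) > 1e-9:
                raise ConfigError("base frequencies must be 4 values summing to 1")
        if not 0 <= self.fail_fraction <= 1:
            raise ConfigError("fail_fraction must be in [0, 1]")


def _random_bases(rng: np.random.Generator, n: int, freqs) -> str:
    return "".join(rng.choice(list(BASES), size=n, p=list(freqs)))


_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}


def _plant_hairpin(
    rng: np.random.Generator, residues: str, stem: int, loop: int
) -> str:
    """Overwrite a random interior segment with a perfect stem-loop."""
    span = 2 * stem + loop
    if span > len(residues):
        raise ConfigError("hairpin longer than sequence")
    start = int(rng.integers(0, len(residues) - span + 1))
    arm = _random_bases(rng, stem, (0.1, 0.4, 0.4, 0.1))  # GC-rich stem
    loop_seq = _random_bases(rng, loop, (0.25, 0.25, 0.25, 0.25))
    rc = "".join(_COMPLEMENT[b] for b in reversed(arm))
    return residues[:start] + arm + loop_seq + rc + residues[start + span :]


def generate_synthetic_assay(
    n_pos: int,
    n_neg: int,
    seq_length: int = 173,
    signal: SignalConfig | None = None,
    rng_seed: int = 0,
) -> list[AssayRecord]:
    """Generate a reproducible synthetic assay table.

    Positives carry the configured U-rich (and optionally hairpin) signal
    with activities above the labeling threshold; negatives sit at or
    below it. When ``signal.fail_fraction`` > 0 that fraction of rows gets
    quality scores failing the splicing/promoter filters.
    """
    if seq_length < 20:
        raise ConfigError("seq_length must be >= 20")
    if n_pos < 0 or n_neg < 0:
        raise ConfigError("counts must be >= 0")
    signal = signal or SignalConfig()
    rng = np.random.default_rng(rng_seed)
    records: list[AssayRecord] = []
    specs = [(True, i) for i in range(n_pos)] + [(False, i) for i in range(n_neg)]
    for is_pos, i in specs:
        freqs = signal.pos_base_freqs if is_pos else signal.neg_base_freqs
        residues = _random_bases(rng, seq_length, freqs)
        if is_pos and signal.hairpin:
            residues = _plant_hairpin(
                rng, residues, signal.hairpin_stem, signal.hairpin_loop
            )
        lo, hi = (
            signal.pos_activity_range if is_pos else signal.neg_activity_range
        )
        activity = float(rng.uniform(lo, hi))
        if rng.uniform() < signal.fail_fraction:
            # fail exactly one quality filter, chosen at random
            if rng.uniform() < 0.5:
                splicing, promoter = float(rng.uniform(-10.0, -2.5)), 0.05
            else:
                splicing, promoter = 0.0, float(rng.uniform(0.2, 1.0))
        else:
            splicing = float(rng.uniform(-2.0, 2.0))
            promoter = float(rng.uniform(0.0, 0.19))
        prefix = "pos" if is_pos else "neg"
        seq_id = f"{prefix}_{i:05d}"
        records.append(
            AssayRecord(
                id=seq_id,
                sequence=RnaSequence(seq_id, residues),
                category="Human_5UTR_Screen",
                ires_activity=activity,
                splicing_score=splicing,
                promoter_activity=promoter,
            )
        )
    return records
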