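"""Configuration objects shared across the pipeline.

Two dataclasses carry every tunable default: :class:`TrimConfig` for the
read-trimming stage and :class:`ScanConfig` for the Poisson scan.  Both can
be round-tripped through a flat YAML key/value file so a whole analysis is
reproducible from one config file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import yaml

#: Window sizes used when the total insertion count is outside the range
#: where the window plan can be derived from the Poisson model itself.
DEFAULT_WINDOWS = (12500, 25000, 50000, 100000, 200000, 301000)


@dataclass(frozen=True)
class TrimConfig:
    """How raw reads are demultiplexed and trimmed.

    transposon_tag is the terminal transposon sequence (IRDR for Sleeping
    Beauty, LTR for proviruses) expected immediately after the barcode;
    linker is the ligation adapter that may trail the genomic fragment.
    """

    transposon_tag: str
    linker: str = ""
    require_ta: bool = True
    barcode_mismatches: int = 0

    def __post_init__(self) -> None:
        if not self.transposon_tag:
            raise ValueError("transposon_tag must be non-empty")
        if self.barcode_mismatches < 0:
            raise ValueError("barcode_mismatches must be >= 0")


@dataclass(frozen=True)
class ScanConfig:
    """Environment of the Poisson scan statistic.

    genome_size is the summed length (bp) of the chromosomes included in
    the analysis; alpha the per-method significance level applied to the
    Bonferroni-corrected p-values; the w_* fields define the window-size
    search grid; small_n/large_n bound the insertion counts for which the
    window plan is derived rather than taken from ``default_windows``;
    bin_size is the width of the insertion-collapsing tiles.
    """

    genome_size: float
    alpha: float = 0.05
    w_min: int = 10_000
    w_max: int = 301_000
    w_step: int = 1_000
    default_windows: Sequence[int] = DEFAULT_WINDOWS
    small_n: int = 2_000
    large_n: int = 200_000
    bin_size: int = 100
    cutoff_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.genome_size <= 0:
            raise ValueError("genome_size must be positive")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0,1)")
        if self.w_min > self.w_max:
            raise ValueError("w_min must be <= w_max")

    def with_genome_size(self, genome_size: float) -> "ScanConfig":
        return replace(self, genome_size=genome_size)


#: Named presets for the clonality read-fraction cutoff, following the
#: platform recommendation: no cutoff for 454-depth data, 1/10,000 of a
#: library's mapped reads for Illumina-depth data.
CUTOFF_PRESETS = {"454": None, "illumina": 1.0 / 10_000}


def save_config(path, trim: TrimConfig | None = None, scan: ScanConfig | None = None) -> None:
    doc: dict = {}
    if trim is not None:
        doc["trim"] = asdict(trim)
    if scan is not None:
        d = asdict(scan)
        d["default_windows"] = list(d["default_windows"])
        doc["scan"] = d
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_config(path) -> tuple[TrimConfig | None, ScanConfig | None]:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    trim = TrimConfig(**doc["trim"]) if "trim" in doc else None
    scan = None
    if "scan" in doc:
        d = dict(doc["scan"])
        if "default_windows" in d:
            d["default_windows"] = tuple(d["default_windows"])
        scan = ScanConfig(**d)
    return trim, scan
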