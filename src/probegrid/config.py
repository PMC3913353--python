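"""Flat key-value run configuration.

One file drives an end-to-end design: design parameters, curation
criteria, alignment/partitioning knobs, and input/output paths.  The
format is ``key = value`` lines (``#`` comments allowed); unknown keys are
rejected so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

from .curation import CurationCriteria
from .seq_core import DesignParameters

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    # design parameters
    probe_length: int = 25
    max_degeneracy: int = 2000
    specificity_threshold: float = 0.88
    max_cross_hyb: int = 100
    job_count: int = 1
    # curation criteria
    min_length: int = 1200
    max_length_prokaryote: int = 1600
    max_length_fungi: int = 1800
    max_unknown_fraction: float = 0.01
    max_unknown_run: int = 5
    require_taxon: bool = True
    # alignment / homogeneity / execution
    large_group_threshold: int = 100
    homogeneity_margin: float = 0.10
    max_retries: int = 2
    max_workers: int = 1
    seed: int = 0
    # paths
    fasta: str = ""
    taxonomy: str = ""
    reference: str = ""
    out_dir: str = "probegrid_out"

    def design_parameters(self) -> DesignParameters:
        return DesignParameters(
            probe_length=self.probe_length,
            max_degeneracy=self.max_degeneracy,
            specificity_threshold=self.specificity_threshold,
            max_cross_hyb=self.max_cross_hyb,
            job_count=self.job_count,
        )

    def curation_criteria(self) -> CurationCriteria:
        return CurationCriteria(
            min_length=self.min_length,
            max_length_prokaryote=self.max_length_prokaryote,
            max_length_fungi=self.max_length_fungi,
            max_unknown_fraction=self.max_unknown_fraction,
            max_unknown_run=self.max_unknown_run,
            require_taxon=self.require_taxon,
        )


def _parse_value(raw: str, typ: type):
    if typ is bool:
        if raw.lower() in ("true", "1", "yes"):
            return True
        if raw.lower() in ("false", "0", "no"):
            return False
        raise ValueError(f"not a boolean: {raw!r}")
    return typ(raw)


def load_config(path: str | Path) -> RunConfig:
    known = {f.name: f.type for f in fields(RunConfig)}
    types = {f.name: type(getattr(RunConfig(), f.name)) for f in fields(RunConfig)}
    values = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, raw = (part.strip() for part in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            values[key] = _parse_value(raw, types[key])
    return RunConfig(**values)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        for key, value in asdict(cfg).items():
            fh.write(f"{key} = {value}\n")
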