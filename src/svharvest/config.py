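"""Pipeline configuration: every detection threshold in one place.

Defaults are tuned for ~120 bp single-end reads at 15-20x depth on a
~100 Mb genome; each is overridable from the CLI or a flat key=value
config file (precedence CLI > file > defaults).
"""

from __future__ import annotations

from dataclasses import dataclass, fields


@dataclass
class PipelineConfig:
    # split-read detection
    min_clip_len: int = 15  # shorter clips realign non-uniquely
    seed_len: int = 12  # exact-seed length for clip realignment
    min_identity: float = 0.95  # ungapped identity over the full clip
    cluster_tolerance: int = 5  # bp slack when merging per-read breakpoints
    min_support: int = 3  # distinct reads per junction at 15-20x

    # copy number
    bin_size: int = 500  # candidate-region interrogation resolution
    del_max: float = 0.25  # hom-deletion ratio ceiling
    dup_min: float = 1.5  # duplication ratio floor
    mult_min: float = 2.5  # multiplication ratio floor
    cn_pseudo: float = 0.05
    control_min: float = 0.25  # mask bins with unreliable control depth
    min_bins: int = 2  # suppress single-bin noise

    # integration
    reciprocal_overlap: float = 0.5
    cn_only_min_len: int = 2000
    hom_min: float = 0.8  # frequency floor for a homozygous call
    het_min: float = 0.25  # below this the call is a likely artifact
    min_strains: int = 2  # strains sharing a variant -> background

    # machine learning
    ml_algorithms: tuple = ("LR", "DT", "kNN", "RF", "LDA", "NB", "SVM")
    ml_seed: int = 0

    def validate(self) -> None:
        if self.min_clip_len < self.seed_len:
            raise ValueError("min_clip_len must be >= seed_len")
        if not self.del_max < self.dup_min < self.mult_min:
            raise ValueError("need del_max < dup_min < mult_min")
        if not 0 < self.het_min < self.hom_min <= 1:
            raise ValueError("need 0 < het_min < hom_min <= 1")
        if not 0 < self.reciprocal_overlap <= 1:
            raise ValueError("reciprocal_overlap must lie in (0,1]")

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        """Flat key=value file; unknown keys are rejected."""
        known = {f.name: f.type for f in fields(cls)}
        values: dict = {}
        with open(path) as fh:
            for line_no, line in enumerate(fh, 1):
                line = line.split("#")[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{line_no}: expected key=value")
                key, _, raw = line.partition("=")
                key, raw = key.strip(), raw.strip()
                if key not in known:
                    raise ValueError(f"{path}:{line_no}: unknown key {key!r}")
                values[key] = _coerce(cls, key, raw)
        values.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**values)
        cfg.validate()
        return cfg


def _coerce(cls, key: str, raw: str):
    default = getattr(cls(), key)
    if isinstance(default, bool):
        return raw.lower() in ("1", "true", "yes")
    if isinstance(default, int):
        return int(raw)
    if isinstance(default, float):
        return float(raw)
    if isinstance(default, tuple):
        return tuple(x.strip() for x in raw.split(","))
    return raw
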