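"""Analysis constants and run configuration.

Every threshold used by the analysis modules is defined exactly once here
and imported by the module that applies it, so that a change in one place
propagates everywhere (CLI, library, tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

#: Number of degree-matched permutation replicates for the proximity null.
N_PERMUTATIONS = 1000

#: Proximity z-score cutoff for calling a drug significantly close to a
#: query gene set (more negative = closer than chance).
Z_CUTOFF = -2.33

#: Benjamini-Hochberg FDR level for gene-overlap repositioning.
BH_ALPHA = 0.05

#: Bonferroni-corrected p cutoff for meta-signature gene calls.
META_THRESHOLD = 0.01

#: Signatures must have strictly more than this many genes to enter
#: network proximity scoring.
MIN_SIGNATURE_GENES = 10

#: Cap applied when truncating a signature to its most significant genes.
SIGNATURE_CAP = 500

#: Toxicity subnetworks smaller than this are filtered out.
MIN_SUBNETWORK_GENES = 10

#: Number of random subsamples per masking proportion in the
#: masking-robustness experiment.
MASKING_REPEATS = 20


@dataclass
class RunConfig:
    """Resolved parameters for one CLI run.

    Defaults mirror the constants above; a plain ``key=value`` config file
    plus command-line flags can override any of them. A copy of the
    resolved configuration is written next to each run's outputs.
    """

    n_perm: int = N_PERMUTATIONS
    seed: int = 0
    cap: int | None = None
    z_cutoff: float = Z_CUTOFF
    bh_alpha: float = BH_ALPHA
    meta_threshold: float = META_THRESHOLD
    min_signature: int = MIN_SIGNATURE_GENES
    min_subnetwork: int = MIN_SUBNETWORK_GENES
    masking_repeats: int = MASKING_REPEATS
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Read ``key=value`` lines (``#`` comments allowed), apply overrides."""
        values: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
            key, _, value = line.partition("=")
            values[key.strip()] = value.strip()
        cfg = cls()
        known = {f for f in cfg.__dataclass_fields__ if f != "extra"}
        for key, value in values.items():
            if key in known:
                current = getattr(cfg, key)
                if key == "cap":
                    setattr(cfg, key, int(value))
                elif isinstance(current, bool):
                    setattr(cfg, key, value.lower() in {"1", "true", "yes"})
                elif isinstance(current, int):
                    setattr(cfg, key, int(value))
                elif isinstance(current, float):
                    setattr(cfg, key, float(value))
                else:
                    setattr(cfg, key, value)
            else:
                cfg.extra[key] = value
        for key, value in overrides.items():
            if value is not None:
                setattr(cfg, key, value)
        return cfg

    def write(self, path: str | Path, timestamp: str | None = None) -> None:
        """Write the resolved configuration as ``key=value`` lines.

        ``timestamp`` adds a suppressible header comment; omit it for
        byte-identical reruns.
        """
        lines = []
        if timestamp is not None:
            lines.append(f"# generated {timestamp}")
        for key, value in asdict(self).items():
            if key == "extra":
                lines.extend(f"{k}={v}" for k, v in value.items())
            elif value is not None:
                lines.append(f"{key}={value}")
        Path(path).write_text("\n".join(lines) + "\n")
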