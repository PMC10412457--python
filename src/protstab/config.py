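"""YAML configuration for kinetic parameters (one block per protease)."""

from __future__ import annotations

from pathlib import Path

import yaml

from .kinetics import ProteolysisParams

DEFAULT_CONFIG = {
    "k_max": 1.0,
    "t_digest_min": 5.0,
    "RT_kcal": 0.593,
    "K50_F_uM": {"trypsin": 500.0, "chymotrypsin": 500.0},
}


def params_from_yaml(path: str | Path | None = None) -> dict[str, ProteolysisParams]:
    """Load per-protease kinetic parameters; defaults apply where unspecified."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        cfg.update(yaml.safe_load(Path(path).read_text()) or {})
    return {
        protease: ProteolysisParams(
            k_max=float(cfg["k_max"]), t_digest=float(cfg["t_digest_min"]),
            RT=float(cfg["RT_kcal"]), K50_F=float(k50f))
        for protease, k50f in cfg["K50_F_uM"].items()
    }
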