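"""Shared plumbing for the numbered analysis drivers."""

from __future__ import annotations

import argparse
from pathlib import Path

import yaml

from gradientscope.synthcohort import SyntheticSpec

ROOT = Path(__file__).resolve().parents[1]


def parse_args(description: str) -> argparse.Namespace:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--config", type=Path, default=ROOT / "analysis" / "config.yaml")
    parser.add_argument("--seed", type=int, default=1)
    return parser.parse_args()


def load_config(path: Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    cfg["paths"]["scratch"] = ROOT / cfg["paths"]["scratch"]
    cfg["paths"]["results"] = ROOT / cfg["paths"]["results"]
    for p in cfg["paths"].values():
        p.mkdir(parents=True, exist_ok=True)
    return cfg


def spec_from_config(cfg: dict, seed: int) -> SyntheticSpec:
    return SyntheticSpec(seed=seed, **cfg["cohort"])
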