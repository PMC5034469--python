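"""Shared plumbing for the numbered analysis drivers."""

import argparse
import json
from pathlib import Path

from agewas.pipeline import PipelineConfig, Run

HERE = Path(__file__).resolve().parent
DEFAULT_CONFIG = HERE / "config.yaml"
DEFAULT_OUTDIR = HERE.parent / "results" / "run"


def get_run(description: str) -> Run:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--config", default=str(DEFAULT_CONFIG),
                    help="YAML pipeline configuration")
    ap.add_argument("--outdir", default=str(DEFAULT_OUTDIR),
                    help="run directory shared by all analysis steps")
    args = ap.parse_args()
    cfg = PipelineConfig.from_yaml(args.config)
    cfg.outdir = args.outdir
    run = Run(cfg)
    run.dir.mkdir(parents=True, exist_ok=True)
    return run


def report(title: str, summary: dict) -> None:
    print(f"== {title} ==")
    print(json.dumps(summary, indent=2, sort_keys=True, default=str))
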