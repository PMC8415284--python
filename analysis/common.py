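"""Shared configuration for the numbered analysis scripts."""

import argparse
import warnings


def baseline_config(seed: int = 42) -> dict:
    return {
        "scenario": "baseline",
        "seed": seed,
        "out_dir": "results/baseline",
        "log_level": "WARNING",
        "grid": {},
        "species": {},
        "resource": {},
        "pool": {},
        "fishing": {},
        "experiments": {},
        "synthetic": {},
    }


def parse_args(description: str) -> dict:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=42)
    args = parser.parse_args()
    warnings.filterwarnings("default")
    return baseline_config(args.seed)
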