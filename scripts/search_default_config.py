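#!/usr/bin/env python
"""Enumerate standard dual-UNet schedules and report the one whose
trainable-parameter count comes closest to the published total.

The winner of this search is frozen as the package's default
``DHuNeTConfig``.  Run from the repository root:

    python scripts/search_default_config.py [--top 10]
"""

import argparse

from dhunet.architecture import build_dhunet, count_parameters
from dhunet.search import PUBLISHED_PARAMETER_COUNT, search_default_schedule


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--top", type=int, default=10)
    args = ap.parse_args()

    candidates = search_default_schedule()
    exact = [c for c in candidates if c.gap == 0]
    print(f"target: {PUBLISHED_PARAMETER_COUNT:,} trainable parameters")
    print(f"schedules enumerated: {len(candidates)}")
    print(f"exact matches: {len(exact)}")
    print()
    hdr = f"{'depth':>5} {'base':>4} {'batchnorm':>9} {'upsample':>11} " \
          f"{'params':>11} {'gap':>7}"
    print(hdr)
    for c in candidates[:args.top]:
        cfg = c.config
        print(f"{cfg.depth:>5} {cfg.base_filters:>4} "
              f"{str(cfg.use_batchnorm):>9} {cfg.upsample_mode:>11} "
              f"{c.parameter_count:>11,} {c.gap:>+7}")
    best = candidates[0]
    built = count_parameters(build_dhunet(best.config, seed=0))
    print()
    print(f"winner built and verified: {built:,} parameters "
          f"({built - PUBLISHED_PARAMETER_COUNT:+} vs published)")


if __name__ == "__main__":
    main()
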