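#!/usr/bin/env python
"""Generate the synthetic 10-trait x 3-outcome study used by the analyses.

Emulates the design of the glioma MR study: ten exposure instrument panels
tested against an all-glioma outcome and two subtype outcomes (shared true
effects, independent sampling noise), with one trait underpowered, one
binary, a correlated SNP pair per panel, and one instrument missing from the
outcome files — so every exclusion path downstream is exercised. True causal
effects are null, as the study concluded for all ten traits.

Writes results/synthetic_run/ (summary-stat tables, LD matrices, config.yaml).
"""

from pathlib import Path

from summarymr import synthetic_data

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "synthetic_run"
SEED = 11


def main() -> None:
    config = synthetic_data.write_run(OUT, n_traits=10, seed=SEED)
    n_files = len(list(OUT.glob("*.tsv")))
    print(f"wrote {n_files} summary-stat/LD tables for "
          f"{len(config.traits)} traits x {len(config.outcomes)} outcomes under {OUT}")
    print(f"run configuration: {OUT / 'config.yaml'} (seed {SEED})")


if __name__ == "__main__":
    main()
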