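#!/usr/bin/env python
"""Generate the study fixtures: paired control/treated contact maps.

Writes three synthetic datasets under results/fixtures/:
  planted/    four 2-Mb regions of inter-domain contact depletion (delta=0.5)
              plus clustered feature peaks inside them,
  null/       two independent samples of the same expected matrix (delta=1),
  compaction/ no planted regions, but a global decay tilt depleting contacts
              beyond 3 Mb in the treated condition.
Each dataset is two contact TSVs, truth BEDs, a chrom-sizes table and a
config echo.  Downstream scripts (02-06) consume these files.
"""

import json
import sys
from pathlib import Path

from hicdelta import simulate_pair, write_bed, write_contact_tsv
from hicdelta.simulate import demo_config

SEED = 7
OUT = Path("results/fixtures")


def write_fixture(name: str, cfg) -> None:
    out = OUT / name
    out.mkdir(parents=True, exist_ok=True)
    sim = simulate_pair(cfg)
    write_contact_tsv(sim.control, out / "control.tsv")
    write_contact_tsv(sim.treated, out / "treated.tsv")
    write_bed(sim.truth_regions, out / "truth_regions.bed")
    write_bed(sim.truth_tads, out / "truth_tads.bed")
    write_bed(sim.feature_peaks, out / "feature_peaks.bed")
    g = cfg.genome
    with open(out / "chrom.sizes", "w") as fh:
        for chrom, length, flag in zip(g.chrom_names, g.chrom_lengths_bp, g.autosome_flags):
            fh.write(f"{chrom}\t{length}\t{int(flag)}\n")
    echo = {
        "bin_size_bp": g.bin_size_bp,
        "alpha": cfg.alpha,
        "beta": cfg.beta,
        "delta": cfg.delta,
        "compaction_shift": cfg.compaction_shift,
        "total_contacts": cfg.total_contacts,
        "seed": cfg.seed,
        "n_truth_regions": len(sim.truth_regions),
        "n_peaks": len(sim.feature_peaks),
    }
    (out / "config_echo.json").write_text(json.dumps(echo, indent=2) + "\n")
    print(f"{name}: {len(sim.truth_regions)} truth regions, "
          f"{len(sim.feature_peaks)} peaks, total ~{int(sim.control.total()):,} contacts")


def main() -> int:
    write_fixture("planted", demo_config(seed=SEED))
    write_fixture("null", demo_config(seed=SEED + 1, delta=1.0))
    write_fixture(
        "compaction",
        demo_config(seed=SEED + 2, planted_pairs=[], compaction_shift=(3_000_000, 0.3)),
    )
    return 0


if __name__ == "__main__":
    sys.exit(main())
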