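#!/usr/bin/env python
"""Genome-wide contact frequencies by distance, via the calibration slope.

Merges four uninduced-background libraries, processes them, computes the
contact-vs-distance curve over intra-chromosomal bin pairs (excluding 50 kb
around every engineered array), and converts the balanced signals into
absolute contact frequencies using the mean intra-chromosomal slope from
step 03.  Both the through-origin and the intercept-subtracting conversion
are reported.

Reads  results/calibration_fits.json  (run analysis/03 first).
Writes results/contact_frequency_vs_distance.tsv.
"""

import json
import sys
from pathlib import Path

import numpy as np

from cici_cal.hicops import (
    distance_decay,
    kr_balance,
    merge_replicates,
    normalize_to_smallest,
    restriction_site_correction,
)
from cici_cal.hicsim import JunctionSpec, simulate_hic
from cici_cal.calibration import signal_to_frequency
from cici_cal.presets import DEMO_N_CONTACTS, DEMO_P_MINUS, demo_bins, demo_model, demo_pairs

SEED = 20260927
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    fits_path = OUT / "calibration_fits.json"
    if not fits_path.exists():
        print("missing results/calibration_fits.json -- run analysis/03 first", file=sys.stderr)
        return 1
    fits = json.loads(fits_path.read_text())
    slope = fits["mean_intra_slope"]
    intra = [pid for pid, f in fits["fits"].items() if pid in ("pair1", "pair3")]
    intercept = float(np.mean([fits["fits"][pid]["intercept"] for pid in intra]))

    model = demo_model()
    bins = demo_bins(seed=SEED)
    pairs = demo_pairs()
    mats = [
        simulate_hic(
            bins, [JunctionSpec(pairs["pair1"], DEMO_P_MINUS)], model, DEMO_N_CONTACTS,
            seed=SEED + rep,
        )
        for rep in range(4)
    ]
    merged = merge_replicates(normalize_to_smallest(mats))
    merged = restriction_site_correction(merged)
    kr_balance(merged)
    exclusions = [
        (p.chrom_a, p.pos_a - 50_000, p.pos_a + 50_000) for p in pairs.values()
    ] + [(p.chrom_b, p.pos_b - 50_000, p.pos_b + 50_000) for p in pairs.values()]
    decay = distance_decay(merged, exclusion_windows=exclusions, use_weights=True)
    decay["contact_frequency"] = signal_to_frequency(decay.mean_signal.to_numpy(), slope)
    decay["contact_frequency_intercept_mode"] = signal_to_frequency(
        decay.mean_signal.to_numpy(), slope, intercept=intercept
    )
    OUT.mkdir(exist_ok=True)
    decay.to_csv(OUT / "contact_frequency_vs_distance.tsv", sep="\t", index=False)

    sel = decay.set_index("separation_bp").contact_frequency
    print("separation   frequency (through-origin)")
    for s in (10_000, 40_000, 100_000, 200_000, 400_000, 700_000):
        if s in sel.index:
            print(f"{s/1000:7.0f} kb   {100*sel[s]:6.2f}%")
    print(
        f"\nFindings: under the Gaussian-chain model, loci within 40 kb touch in "
        f"~{100*sel[40_000]:.0f}% of cells while ~700 kb separations contact in "
        f"~{100*sel[700_000]:.1f}% -- short-range proximity is near-ubiquitous, "
        f"long-range contact is rare. The intercept-subtracting conversion lowers "
        f"all frequencies by ~{100*intercept/slope:.1f} points."
    )
    return 0


if __name__ == "__main__":
    sys.exit(main())
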