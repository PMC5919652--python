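"""MRI-arm lesion volumetry over 50 noise realizations.

For each seed: simulate the 19-image acquisition at SNR 50, fit MD/MKT,
segment both lesions (k = 2 against the contralateral hemisphere, half-way
boundary refinement), and tabulate volumes.  The headline number is the
mean percentage excess of the MKT lesion volume over the MD lesion volume,
which the phantom design pins at ~31%.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from fastdki import (
    default_spec,
    dice,
    fit_maps,
    generate_phantom,
    mismatch_percent,
    segment_lesion,
    simulate_acquisition,
    volume_from_mask,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
N_SEEDS = 50


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    spec = default_spec()
    truth = generate_phantom(spec)
    vx = spec.voxel_size_mm
    v_true = {k: volume_from_mask(truth.masks[k], vx)
              for k in ("lesion_md", "lesion_mkt")}

    rows = []
    for seed in range(1, N_SEEDS + 1):
        series = simulate_acquisition(truth, snr=spec.snr, seed=seed)
        md_map, mkt_map = fit_maps(series, truth.masks["brain"])
        les_md = segment_lesion(md_map, truth.masks["brain"],
                                truth.masks["left"], "md_low", 2.0)
        les_mkt = segment_lesion(mkt_map, truth.masks["brain"],
                                 truth.masks["left"], "mkt_high", 2.0)
        v_md = volume_from_mask(les_md, vx)
        v_mkt = volume_from_mask(les_mkt, vx)
        rows.append({
            "seed": seed,
            "volume_md_cm3": v_md,
            "volume_mkt_cm3": v_mkt,
            "excess_percent": mismatch_percent(v_mkt, v_md),
            "dice_md": dice(les_md.mask, truth.masks["lesion_md"]),
            "dice_mkt": dice(les_mkt.mask, truth.masks["lesion_mkt"]),
        })
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "lesion_volumes_mri.csv", index=False)

    print(f"truth: MD {v_true['lesion_md']:.4f} cm^3, "
          f"MKT {v_true['lesion_mkt']:.4f} cm^3 "
          f"(designed excess {mismatch_percent(v_true['lesion_mkt'], v_true['lesion_md']):.1f}%)")
    print(f"recovered over {N_SEEDS} seeds:")
    print(f"  MD  volume {table.volume_md_cm3.mean():.4f} +/- {table.volume_md_cm3.std():.4f} cm^3")
    print(f"  MKT volume {table.volume_mkt_cm3.mean():.4f} +/- {table.volume_mkt_cm3.std():.4f} cm^3")
    print(f"  excess {table.excess_percent.mean():.2f} +/- {table.excess_percent.std():.2f} %")
    print(f"  Dice   MD >= {table.dice_md.min():.3f}, MKT >= {table.dice_mkt.min():.3f}")


if __name__ == "__main__":
    main()
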