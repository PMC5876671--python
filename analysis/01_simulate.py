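"""Stage 1 — generate synthetic litchi captures.

Writes a small inspectable batch (ENVI cubes, reference frames, mask PNGs,
manifest) under scratch/demo_batch and a per-sample summary table under
results/.  The full-scale sets used by later stages are re-generated
deterministically from the same seeds, so nothing large needs to persist.
"""

from pathlib import Path

import pandas as pd

from litchi_hsi import synth

SEED = 42
RESULTS = Path("results")
SCRATCH = Path("scratch/demo_batch")


def main() -> None:
    samples = synth.generate_dataset(2, seed=SEED, id_prefix="demo")
    manifest = synth.write_dataset(samples, SCRATCH)
    rows = []
    for s in samples:
        cube = s.calibrated()
        idx = cube.axis.nearest_index(725)
        band = cube.data[:, :, idx]
        rows.append({
            "sample_id": s.sample_id,
            "label": s.label,
            "quality": synth.QUALITY_NAMES[s.label],
            "fruit_px": int(s.fruit_mask.sum()),
            "damage_px": int(s.damage_mask.sum()),
            "fruit_R725": round(float(band[s.fruit_mask].mean()), 4),
            "damage_R725": round(float(band[s.damage_mask].mean()), 4)
            if s.damage_mask.any() else float("nan"),
        })
    df = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "simulation_summary.csv", index=False)
    print(f"wrote {len(samples)} demo cubes to {SCRATCH} (manifest: {manifest})")
    print(df.to_string(index=False))
    print("\nNote the monotone drop of damage-region reflectance at 725 nm "
          "with damage age — the contrast every later stage exploits.")


if __name__ == "__main__":
    main()
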