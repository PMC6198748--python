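#!/usr/bin/env python
"""Generate the synthetic raw-data cohort used by the downstream drivers.

Writes, per fibril, under results/raw/: the lateral-force and video-deflection
CSVs of the bowstring pull, pre- and post-rupture AFM height maps, the
polarization-resolved SHG stack of the ruptured fibril plus an intact control
stack, and a two-channel CHP fluorescence image; plus the cantilever sheet and
a cohort.yaml pipeline configuration.
"""

from pathlib import Path

import numpy as np
import tifffile
import yaml

from fibrilmech import cantilever, dataset_io, shg, synth

OUT = Path(__file__).resolve().parent.parent / "results" / "raw"

# Four fibrils spanning both animals and both tendon types.  Ruptured
# fibrils carry a lowered anisotropy and kinks; the common digital extensor
# pair also reads fluorescence-positive.
COHORT = [
    # id,    rho_rupt, phi, kinks (nm),          fluor+, seed
    ("1e1", 1.30, 20.0, (12000.0, 21000.0), True, 101),
    ("1f1", 1.45, 55.0, (15000.0,), False, 102),
    ("2e1", 1.25, 110.0, (9000.0, 17000.0, 26000.0), True, 103),
    ("2f1", 1.50, 160.0, (), False, 104),
]

RHO_CONTROL = 1.65          # intact-fibril anisotropy
AMP_RUPTURED = 5000.0       # SHG amplitudes chosen so ruptured/control < 1
AMP_CONTROL = 7000.0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cantilever.write_cantilever_sheet(
        [cantilever.CantileverSpec(number=1)], OUT / "cantilevers.csv")

    entries = []
    for fid, rho, phi, kinks, fluor_pos, seed in COHORT:
        truth = synth.FibrilGroundTruth(rho_true=rho,
                                        fibril_angle_phi_deg=phi)
        exp = synth.make_pull_experiment(truth, seed=seed)
        fpath, vpath = OUT / f"{fid}_force.csv", OUT / f"{fid}_video.csv"
        dataset_io.write_pull_experiment(exp, fpath, vpath)

        # post-rupture AFM: shorter recovered segment, kinked, slightly
        # shrunken; pre-rupture map is straight at the full radius
        before_truth = synth.FibrilGroundTruth(segment_length_um=30.0)
        after_truth = synth.FibrilGroundTruth(
            segment_length_um=30.0, dry_radius_nm=85.0,
            kink_positions_nm=kinks)
        before = synth.make_afm_map(before_truth, noise_sd_nm=0.4,
                                    seed=seed + 10)
        after = synth.make_afm_map(after_truth, noise_sd_nm=0.4,
                                   seed=seed + 20)
        bpath, apath = OUT / f"{fid}_afm_before.tif", OUT / f"{fid}_afm_after.tif"
        tifffile.imwrite(bpath, before.heights_nm.astype(np.float32))
        tifffile.imwrite(apath, after.heights_nm.astype(np.float32))

        # SHG pol-stacks: a fibril band across the field of view
        band = synth.rectangle_mask((40, 120), 16, 24, 0, 120)
        stack = synth.make_polstack(rho * band, phi, amplitude=AMP_RUPTURED,
                                    seed=seed + 30)
        cstack = synth.make_polstack(RHO_CONTROL * band, phi,
                                     amplitude=AMP_CONTROL, seed=seed + 40)
        ppath, cpath = OUT / f"{fid}_pol.tif", OUT / f"{fid}c_pol.tif"
        shg.write_polstack(stack, ppath)
        shg.write_polstack(cstack, cpath)

        # CHP fluorescence: positive fibrils sit well above background
        fmask = synth.rectangle_mask((80, 80), 34, 44, 0, 80)
        img = synth.make_fluorescence_image(
            fmask, fibril_level=500.0 if fluor_pos else 105.0,
            background_level=100.0, noise_sd=10.0, seed=seed + 50)
        flpath = OUT / f"{fid}_fluor.tif"
        tifffile.imwrite(flpath, np.stack(
            [img.brightfield, img.fluorescence]).astype(np.float32))

        entries.append({
            "id": fid,
            "length_um": truth.segment_length_um,
            "dry_area_um2": truth.dry_area_um2,
            "cantilever": 1,
            "force_file": str(fpath), "video_file": str(vpath),
            "afm_before": str(bpath), "afm_after": str(apath),
            "polstack": str(ppath), "polstack_control": str(cpath),
            "fluorescence": str(flpath),
        })

    (OUT / "cohort.yaml").write_text(yaml.safe_dump({"fibrils": entries}))
    print(f"wrote {len(entries)} fibrils to {OUT}")


if __name__ == "__main__":
    main()
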