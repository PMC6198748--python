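"""Readers/writers for the deposition's tabular schemas, and orchestration.

The deposition's worksheets are mirrored as delimited text: the tensile
summary (animal, tendon, fibril, geometry, four mechanical parameters), the
per-fibril two-column stress-strain files, and the post-rupture imaging
summary (heights, kinks, fluorescence call, SHG ratio and anisotropy
statistics).  Fibrils are identified by ``<animal><tendon><fibril>`` with
tendon ``e`` (common digital extensor) or ``f`` (superficial digital
flexor), e.g. ``1e1``; a control pol-stack carries the suffix ``c``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import afm, fluorescence, mechanics, shg
from .mechanics import MechanicalSummary, StressStrainCurve

TENDON_CODES = ("e", "f")

_ID_RE = re.compile(r"^([12])([ef])(\d+)$")


def format_fibril_id(animal: int, tendon: str, fibril: int) -> str:
    if tendon not in TENDON_CODES:
        raise ValueError(f"tendon code must be one of {TENDON_CODES}")
    if animal not in (1, 2):
        raise ValueError("animal number must be 1 or 2")
    if fibril < 1:
        raise ValueError("fibril number must be positive")
    return f"{animal}{tendon}{fibril}"


def parse_fibril_id(fid: str) -> tuple[int, str, int]:
    m = _ID_RE.match(fid)
    if not m:
        raise ValueError(f"malformed fibril id {fid!r}; expected e.g. '1e1'")
    return int(m.group(1)), m.group(2), int(m.group(3))


# ---------------------------------------------------------------- File 1

TENSILE_COLUMNS = [
    "animal", "tendon", "fibril", "length_um", "dry_area_um2",
    "cantilever_number", "rupture_strain_pct", "rupture_stress_mpa",
    "toughness_mj_m3", "high_strain_modulus_mpa", "modulus_error_mpa",
]


@dataclass
class FibrilRecord:
    """One fibril's identity, geometry and analysis results."""

    animal: int
    tendon: str
    fibril: int
    length_um: float = np.nan
    dry_area_um2: float = np.nan
    cantilever_number: int = 1
    mechanical: MechanicalSummary | None = None
    post_rupture: dict = field(default_factory=dict)

    @property
    def fid(self) -> str:
        return format_fibril_id(self.animal, self.tendon, self.fibril)


def write_tensile_table(records: list[FibrilRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        m = r.mechanical
        rows.append({
            "animal": r.animal, "tendon": r.tendon, "fibril": r.fibril,
            "length_um": r.length_um, "dry_area_um2": r.dry_area_um2,
            "cantilever_number": r.cantilever_number,
            "rupture_strain_pct": m.rupture_strain_pct if m else np.nan,
            "rupture_stress_mpa": m.rupture_stress_mpa if m else np.nan,
            "toughness_mj_m3": m.toughness_mj_m3 if m else np.nan,
            "high_strain_modulus_mpa": m.high_strain_modulus_mpa if m else np.nan,
            "modulus_error_mpa": m.modulus_error_mpa if m else np.nan,
        })
    pd.DataFrame(rows, columns=TENSILE_COLUMNS).to_csv(
        path, index=False, float_format="%.10g")


def read_tensile_table(path: str | Path) -> list[FibrilRecord]:
    df = pd.read_csv(path)
    missing = [c for c in TENSILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"tensile table missing columns: {missing}")
    records = []
    for i, row in df.iterrows():
        tendon = str(row["tendon"])
        if tendon not in TENDON_CODES:
            raise ValueError(f"row {i}, column 'tendon': invalid code "
                             f"{tendon!r} (must be one of {TENDON_CODES})")
        mech = MechanicalSummary(
            rupture_strain_pct=float(row["rupture_strain_pct"]),
            rupture_stress_mpa=float(row["rupture_stress_mpa"]),
            toughness_mj_m3=float(row["toughness_mj_m3"]),
            high_strain_modulus_mpa=float(row["high_strain_modulus_mpa"]),
            modulus_error_mpa=float(row["modulus_error_mpa"]),
        )
        records.append(FibrilRecord(
            animal=int(row["animal"]), tendon=tendon,
            fibril=int(row["fibril"]), length_um=float(row["length_um"]),
            dry_area_um2=float(row["dry_area_um2"]),
            cantilever_number=int(row["cantilever_number"]),
            mechanical=mech))
    return records


# ---------------------------------------------------------------- File 3

def write_stress_strain(curve: StressStrainCurve, fid: str,
                        out_dir: str | Path) -> Path:
    """Two-column tab-delimited (strain %, stress MPa) file named by id."""
    parse_fibril_id(fid)
    path = Path(out_dir) / fid
    np.savetxt(path, np.column_stack([curve.strain_pct, curve.stress_mpa]),
               delimiter="\t", fmt="%.17g")
    return path


def read_stress_strain(path: str | Path) -> StressStrainCurve:
    data = np.loadtxt(path, delimiter="\t", ndmin=2)
    return StressStrainCurve(strain_pct=data[:, 0], stress_mpa=data[:, 1])


# ---------------------------------------------------------------- File 4

POST_RUPTURE_COLUMNS = [
    "animal", "tendon", "fibril", "rupture_location",
    "mean_height_before_nm", "height_loss_nm", "height_loss_pct",
    "kink_count", "kink_mean_spacing_nm", "fluorescent_above_background",
    "shg_intensity_ratio", "rho_peak_ruptured", "rho_fwhm_ruptured",
    "rho_peak_control", "rho_fwhm_control",
]


def write_post_rupture_table(records: list[FibrilRecord],
                             path: str | Path) -> None:
    rows = []
    for r in records:
        p = r.post_rupture
        row = {"animal": r.animal, "tendon": r.tendon, "fibril": r.fibril}
        for col in POST_RUPTURE_COLUMNS[3:]:
            row[col] = p.get(col, np.nan)
        rows.append(row)
    pd.DataFrame(rows, columns=POST_RUPTURE_COLUMNS).to_csv(
        path, index=False, float_format="%.10g")


def read_post_rupture_table(path: str | Path) -> list[FibrilRecord]:
    df = pd.read_csv(path)
    missing = [c for c in POST_RUPTURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"post-rupture table missing columns: {missing}")
    records = []
    for i, row in df.iterrows():
        tendon = str(row["tendon"])
        if tendon not in TENDON_CODES:
            raise ValueError(f"row {i}, column 'tendon': invalid code "
                             f"{tendon!r}")
        post = {c: row[c] for c in POST_RUPTURE_COLUMNS[3:]}
        records.append(FibrilRecord(animal=int(row["animal"]), tendon=tendon,
                                    fibril=int(row["fibril"]),
                                    post_rupture=post))
    return records


# ------------------------------------------------------- pull experiment IO

def write_pull_experiment(exp: mechanics.PullExperiment, force_path, video_path
                          ) -> None:
    pd.DataFrame({"time_s": exp.force_time_s,
                  "force_un": exp.force_un}).to_csv(
        force_path, index=False, float_format="%.17g")
    pd.DataFrame({"time_s": exp.video_time_s,
                  "deflection_um": exp.deflection_um}).to_csv(
        video_path, index=False, float_format="%.17g")


def read_pull_experiment(force_path, video_path, length_um: float,
                         dry_area_um2: float,
                         rupture_frame_index: int = -1
                         ) -> mechanics.PullExperiment:
    f = pd.read_csv(force_path, float_precision="round_trip")
    v = pd.read_csv(video_path, float_precision="round_trip")
    return mechanics.PullExperiment(
        force_time_s=f["time_s"].to_numpy(),
        force_un=f["force_un"].to_numpy(),
        video_time_s=v["time_s"].to_numpy(),
        deflection_um=v["deflection_um"].to_numpy(),
        segment_length_um=length_um, dry_area_um2=dry_area_um2,
        rupture_frame_index=rupture_frame_index)


# ------------------------------------------------------------- pipeline

def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "fibrils" not in cfg:
        raise ValueError("config must be a mapping with a 'fibrils' list")
    for entry in cfg["fibrils"]:
        parse_fibril_id(str(entry.get("id", "")))
        for key in ("length_um", "dry_area_um2"):
            if key not in entry:
                raise ValueError(f"fibril {entry.get('id')}: missing {key}")
    return cfg


def _video_rupture_frame(video_time: np.ndarray, force_time: np.ndarray,
                         rupture_force_index: int) -> int:
    """Last frame at or before the detected force-trace rupture instant.

    Stands in for the manual video identification when the two synthetic
    records share a time origin.
    """
    t = force_time[rupture_force_index]
    return int(np.searchsorted(video_time, t, side="right") - 1)


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Execute the full per-fibril workflow and write the summary tables.

    For every configured fibril: tensile analysis to a stress-strain file
    and mechanical parameters; AFM morphometry (height loss, kinks); SHG
    anisotropy and intensity ratio; fluorescence call.  Stage failures are
    recorded per fibril and the pipeline continues.  Deterministic given
    inputs and config.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    curves_dir = out_dir / "stress_strain"
    curves_dir.mkdir(exist_ok=True)

    records: list[FibrilRecord] = []
    log: list[str] = []
    failures: dict[str, list[str]] = {}

    for entry in config["fibrils"]:
        fid = str(entry["id"])
        animal, tendon, fibril = parse_fibril_id(fid)
        rec = FibrilRecord(animal=animal, tendon=tendon, fibril=fibril,
                           length_um=float(entry["length_um"]),
                           dry_area_um2=float(entry["dry_area_um2"]),
                           cantilever_number=int(entry.get("cantilever", 1)))
        rec.post_rupture["rupture_location"] = entry.get(
            "rupture_location", "middle")
        errs = []

        # --- mechanics
        if entry.get("force_file") and entry.get("video_file"):
            try:
                exp = read_pull_experiment(
                    entry["force_file"], entry["video_file"],
                    rec.length_um, rec.dry_area_um2,
                    rupture_frame_index=int(entry.get("rupture_frame", -1)))
                if exp.rupture_frame_index < 0:
                    k = mechanics.detect_rupture(exp.force_un)
                    exp.rupture_frame_index = _video_rupture_frame(
                        exp.video_time_s, exp.force_time_s, k)
                curve, summary = mechanics.analyze_pull(exp)
                rec.mechanical = summary
                write_stress_strain(curve, fid, curves_dir)
                log.append(f"{fid} mechanics ok: rupture "
                           f"{summary.rupture_strain_pct:.2f}% / "
                           f"{summary.rupture_stress_mpa:.1f} MPa")
            except Exception as exc:      # record and continue
                errs.append(f"mechanics: {exc}")

        # --- AFM
        if entry.get("afm_after"):
            try:
                import tifffile
                after = afm.HeightMap(tifffile.imread(entry["afm_after"]),
                                      pixel_size_nm=float(
                                          entry.get("pixel_nm", 8.0)))
                kinks = afm.detect_kinks(after)
                rec.post_rupture["kink_count"] = kinks.count
                rec.post_rupture["kink_mean_spacing_nm"] = kinks.mean_spacing_nm
                if entry.get("afm_before"):
                    before = afm.HeightMap(
                        tifffile.imread(entry["afm_before"]),
                        pixel_size_nm=float(entry.get("pixel_nm", 8.0)))
                    hb, loss, norm = afm.height_loss(before, after)
                    rec.post_rupture["mean_height_before_nm"] = hb
                    rec.post_rupture["height_loss_nm"] = loss
                    rec.post_rupture["height_loss_pct"] = norm
                log.append(f"{fid} afm ok: {kinks.count} kinks")
            except Exception as exc:
                errs.append(f"afm: {exc}")

        # --- SHG
        if entry.get("polstack"):
            try:
                stack = shg.read_polstack(entry["polstack"])
                mmap = shg.max_intensity_map(stack)
                mask = shg.fibril_mask_from_max(mmap)
                res = shg.rho_map(stack, mask)
                peak, fwhm = shg.rho_distribution(res)
                rec.post_rupture["rho_peak_ruptured"] = peak
                rec.post_rupture["rho_fwhm_ruptured"] = fwhm
                if entry.get("polstack_control"):
                    cstack = shg.read_polstack(entry["polstack_control"])
                    cmap = shg.max_intensity_map(cstack)
                    cmask = shg.fibril_mask_from_max(cmap)
                    cres = shg.rho_map(cstack, cmask)
                    cpeak, cfwhm = shg.rho_distribution(cres)
                    rec.post_rupture["rho_peak_control"] = cpeak
                    rec.post_rupture["rho_fwhm_control"] = cfwhm
                    rec.post_rupture["shg_intensity_ratio"] = \
                        shg.intensity_ratio(mmap, cmap, mask, cmask)
                log.append(f"{fid} shg ok: rho peak {peak:.3f}")
            except Exception as exc:
                errs.append(f"shg: {exc}")

        # --- fluorescence
        if entry.get("fluorescence"):
            try:
                import tifffile
                channels = tifffile.imread(entry["fluorescence"])
                img = fluorescence.FluorImage(
                    brightfield=channels[0], fluorescence=channels[1])
                fmask, bmask = fluorescence.mask_from_brightfield(
                    img.brightfield)
                call, margin = fluorescence.classify_fibril(img, fmask, bmask)
                rec.post_rupture["fluorescent_above_background"] = \
                    "Yes" if call else "No"
                log.append(f"{fid} fluorescence ok: "
                           f"{'Yes' if call else 'No'} (margin {margin:.2f})")
            except Exception as exc:
                errs.append(f"fluorescence: {exc}")

        if errs:
            failures[fid] = errs
            log.extend(f"{fid} FAILED {e}" for e in errs)
        records.append(rec)

    write_tensile_table([r for r in records], out_dir / "tensile_data.csv")
    write_post_rupture_table(records, out_dir / "post_rupture_data.csv")
    (out_dir / "pipeline.log").write_text("\n".join(log) + "\n")
    return {"records": records, "failures": failures, "log": log,
            "out_dir": out_dir}
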