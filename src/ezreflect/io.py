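"""File formats: TIFF volumes with JSON sidecars, CSV surfaces/maps/tables,
PNG previews and QC overlays.

Output layout is deliberately open and text-first: volumes are multi-page
TIFF plus a JSON sidecar with scales and seeds; segmentation surfaces go to
long-format CSV (bscan, ascan, layer, row); the rEZR map to CSV with
per-ROI geometry and exclusion causes; model results to a Table-style CSV.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .quantify import LAYER_NAMES, OCTVolume, REZRMap, SegmentationSurfaces


def sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------


def save_volume(volume: OCTVolume, tiff_path: str | Path, extra: dict | None = None) -> None:
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, volume.intensities.astype(np.float32))
    sidecar = {
        "axial_scale_um": volume.axial_scale,
        "lateral_scale_um": volume.lateral_scale,
        "bscan_spacing_um": volume.bscan_spacing,
        "fovea_center": list(volume.fovea_center),
        **(extra or {}),
    }
    tiff_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_volume(tiff_path: str | Path) -> OCTVolume:
    tiff_path = Path(tiff_path)
    data = np.asarray(tifffile.imread(tiff_path), dtype=float)
    side = json.loads(tiff_path.with_suffix(".json").read_text())
    return OCTVolume(
        intensities=np.clip(data, 0.0, 1.0),
        axial_scale=side["axial_scale_um"],
        lateral_scale=side["lateral_scale_um"],
        bscan_spacing=side["bscan_spacing_um"],
        fovea_center=tuple(side["fovea_center"]),
    )


# ---------------------------------------------------------------------------
# surfaces
# ---------------------------------------------------------------------------


def save_surfaces(surfaces: SegmentationSurfaces, path: str | Path) -> None:
    B, W = surfaces.shape
    frames = []
    for layer in LAYER_NAMES:
        arr = surfaces.layer(layer)
        b, a = np.meshgrid(np.arange(B), np.arange(W), indexing="ij")
        frames.append(
            pd.DataFrame(
                {"bscan": b.ravel(), "ascan": a.ravel(), "layer": layer, "row": arr.ravel()}
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def load_surfaces(path: str | Path) -> SegmentationSurfaces:
    df = pd.read_csv(path)
    B = int(df["bscan"].max()) + 1
    W = int(df["ascan"].max()) + 1
    rows = {}
    for layer, g in df.groupby("layer"):
        arr = np.full((B, W), np.nan)
        arr[g["bscan"].to_numpy(), g["ascan"].to_numpy()] = g["row"].to_numpy()
        rows[layer] = arr
    return SegmentationSurfaces(rows=rows)


# ---------------------------------------------------------------------------
# rEZR maps
# ---------------------------------------------------------------------------


def save_map(rezr_map: REZRMap, path: str | Path) -> None:
    B, n_rois = rezr_map.shape
    combined = rezr_map.combined_exclusions
    kind = np.full((B, n_rois), "", dtype=object)
    for name, flags in rezr_map.exclusions.items():
        sel = flags & (kind == "")
        kind[sel] = name
    b, r = np.meshgrid(np.arange(B), np.arange(n_rois), indexing="ij")
    pd.DataFrame(
        {
            "bscan": b.ravel(),
            "roi_index": r.ravel(),
            "x_deg": np.broadcast_to(rezr_map.x_deg, (B, n_rois)).ravel(),
            "y_deg": np.broadcast_to(rezr_map.y_deg[:, None], (B, n_rois)).ravel(),
            "rezr": rezr_map.values.ravel(),
            "excluded": combined.ravel(),
            "exclusion_kind": kind.ravel(),
        }
    ).to_csv(path, index=False, float_format="%.6g")


def load_map(path: str | Path, degrees_to_um: float = 288.0) -> REZRMap:
    df = pd.read_csv(path)
    B = int(df["bscan"].max()) + 1
    n_rois = int(df["roi_index"].max()) + 1
    values = np.full((B, n_rois), np.nan)
    values[df["bscan"], df["roi_index"]] = df["rezr"]
    exclusions = {}
    for kind in ("drusen", "atrophy", "no_segmentation", "edge"):
        flags = np.zeros((B, n_rois), dtype=bool)
        sel = df["exclusion_kind"] == kind
        flags[df.loc[sel, "bscan"], df.loc[sel, "roi_index"]] = True
        exclusions[kind] = flags
    x_deg = df.drop_duplicates("roi_index").sort_values("roi_index")["x_deg"].to_numpy()
    y_deg = df.drop_duplicates("bscan").sort_values("bscan")["y_deg"].to_numpy()
    values[
        np.stack([exclusions[k] for k in exclusions]).any(axis=0)
    ] = np.nan
    return REZRMap(
        values=values,
        exclusions=exclusions,
        x_um=x_deg * degrees_to_um,
        y_um=y_deg * degrees_to_um,
        degrees_to_um=degrees_to_um,
    )


def save_map_png(rezr_map: REZRMap, path: str | Path, samples: pd.DataFrame | None = None) -> None:
    """Red-to-green en-face heat map; optionally superimposes point-wise
    sensitivities (dB) from an aligned-samples table."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    extent = [
        rezr_map.x_deg[0], rezr_map.x_deg[-1], rezr_map.y_deg[-1], rezr_map.y_deg[0]
    ]
    masked = np.ma.masked_invalid(rezr_map.values)
    cmap = plt.get_cmap("RdYlGn").copy()
    cmap.set_bad("0.6")
    im = ax.imshow(masked, cmap=cmap, extent=extent, aspect="equal")
    fig.colorbar(im, ax=ax, label="rEZR (AU)")
    if samples is not None:
        sc = ax.scatter(
            samples["x_deg"],
            samples["y_deg"],
            c=samples.get("sensitivity_db"),
            cmap="RdYlGn",
            vmin=0,
            vmax=36,
            edgecolors="k",
            s=60,
        )
        for _, row in samples.iterrows():
            if "sensitivity_db" in row and np.isfinite(row["sensitivity_db"]):
                ax.annotate(
                    f"{row['sensitivity_db']:.0f}",
                    (row["x_deg"], row["y_deg"]),
                    fontsize=6,
                    ha="center",
                    va="bottom",
                )
        fig.colorbar(sc, ax=ax, label="sensitivity (dB)")
    ax.set_xlabel("x (deg)")
    ax.set_ylabel("y (deg)")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_overlay_png(overlay_rgb: np.ndarray, path: str | Path) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, (np.clip(overlay_rgb, 0, 1) * 255).astype(np.uint8))


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


def save_cohort(cohort, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cohort.participants.to_csv(directory / "participants.csv", index=False)
    cohort.points.to_csv(directory / "points.csv", index=False)


def load_cohort(directory: str | Path):
    from .phantom import CohortTable

    directory = Path(directory)
    return CohortTable(
        participants=pd.read_csv(directory / "participants.csv"),
        points=pd.read_csv(directory / "points.csv"),
    )


def save_result(result, path: str | Path) -> None:
    """Model result as CSV (predictor, CE, CI bounds, p) at 4 significant
    figures, matching the granularity of published coefficient tables."""
    df = result.to_frame()
    for col in ("estimate", "ci_low", "ci_high", "p"):
        df[col] = df[col].map(lambda v: float(f"{v:.4g}"))
    df.to_csv(path, index=False)
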