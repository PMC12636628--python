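"""Plot-ready data computation and result bundling.

Everything here is pure and deterministic: Miami-plot frames (mirrored
female/male Manhattan data with p truncation), multi-tag locus points
(each variant's LD to three index variants encoded as size and a color
class), and a reproducible results bundle with a config snapshot, seed
registry and per-file checksums. Rendering to SVG is a thin optional layer
with no computed semantics.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MultiTagPoint", "multitag_plot_data", "miami_plot_data",
    "results_bundle", "verify_bundle", "render_multitag_svg",
]

R2_COLOR_MIN = 0.2


@dataclass
class MultiTagPoint:
    variant_id: str
    pos: int
    neglog10p: float
    size_r2: float
    color_class: str          # tag1 | tag2 | tag3 | blend | gray
    blend_weights: tuple | None = None


def multitag_plot_data(variants: pd.DataFrame, tags: list[str],
                       ld_lookup) -> list[MultiTagPoint]:
    """Per-variant multi-tag LD encoding for a three-signal locus.

    Size is the max r2 across the 3 tags; color is tag k when r2 >= 0.2
    with exactly that tag, a blend (weights = per-tag r2 normalized over
    qualifying tags) with several, gray with none.
    """
    if len(tags) != 3:
        raise ValueError("exactly 3 tagging variants required")
    ids = variants["variant_id"].tolist()
    r2 = np.column_stack([ld_lookup.r2_with(t, ids) for t in tags])
    points = []
    for i, row in enumerate(variants.itertuples(index=False)):
        r = r2[i]
        qualifying = np.flatnonzero(r >= R2_COLOR_MIN)
        if len(qualifying) == 0:
            color, weights = "gray", None
        elif len(qualifying) == 1:
            color, weights = f"tag{qualifying[0] + 1}", None
        else:
            color = "blend"
            w = r[qualifying] / r[qualifying].sum()
            full = np.zeros(3)
            full[qualifying] = w
            weights = tuple(full)
        points.append(MultiTagPoint(
            variant_id=row.variant_id, pos=int(row.pos),
            neglog10p=float(-np.log10(max(row.p, 5e-324))),
            size_r2=float(r.max()), color_class=color,
            blend_weights=weights))
    return points


def miami_plot_data(female_table: pd.DataFrame,
                    male_table: pd.DataFrame | None,
                    truncate_p: float = 1e-30,
                    gw_line: float = 5e-8,
                    lead_annotations: pd.DataFrame | None = None) -> pd.DataFrame:
    """Mirrored Manhattan frame: -log10 p capped at the truncation level,
    female values positive, male values negative; the genome-wide line and
    lead-variant labels are attached as columns."""
    cap = -np.log10(truncate_p)
    frames = []
    for table, sex, sign in ((female_table, "female", 1.0),
                             (male_table, "male", -1.0)):
        if table is None:
            import warnings
            warnings.warn(f"no {sex} table; one-sided Miami frame",
                          stacklevel=2)
            continue
        df = table[["variant_id", "chrom", "pos", "p"]].copy()
        df["sex"] = sex
        df["neglog10p"] = np.minimum(
            -np.log10(np.maximum(df["p"], 5e-324)), cap)
        df["y"] = sign * df["neglog10p"]
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["gw_line"] = -np.log10(gw_line)
    out["lead_label"] = ""
    if lead_annotations is not None and len(lead_annotations):
        labels = lead_annotations.set_index("variant_id")["label"]
        out["lead_label"] = out["variant_id"].map(labels).fillna("")
    return out


# ---------------------------------------------------------------------------
# results bundle

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def results_bundle(outputs: dict[str, pd.DataFrame | dict], outdir: str | Path,
                   config: dict, seeds: dict[str, int],
                   run_log: list[str] | None = None) -> Path:
    """Write all stage outputs plus config snapshot, seed registry, and a
    checksum manifest. Reruns with identical config and seeds reproduce
    byte-identical tables. Missing stage outputs (None values) raise."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    missing = [k for k, v in outputs.items() if v is None]
    if missing:
        raise ValueError(f"missing stage outputs: {missing}")
    written = []
    for name, obj in sorted(outputs.items()):
        if isinstance(obj, pd.DataFrame):
            path = outdir / f"{name}.tsv"
            obj.to_csv(path, sep="\t", index=False, float_format="%.10g")
        else:
            path = outdir / f"{name}.json"
            path.write_text(json.dumps(obj, indent=2, sort_keys=True,
                                       default=str) + "\n")
        written.append(path)
    (outdir / "config.json").write_text(
        json.dumps(config, indent=2, sort_keys=True) + "\n")
    (outdir / "seeds.json").write_text(
        json.dumps(seeds, indent=2, sort_keys=True) + "\n")
    (outdir / "run.log").write_text("\n".join(run_log or []) + "\n")
    manifest = {p.name: _sha256(p) for p in written
                + [outdir / "config.json", outdir / "seeds.json"]}
    (outdir / "MANIFEST.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return outdir


def verify_bundle(outdir: str | Path) -> dict[str, bool]:
    """Recompute checksums against the manifest; False marks tampering."""
    outdir = Path(outdir)
    manifest = json.loads((outdir / "MANIFEST.json").read_text())
    return {name: (outdir / name).exists()
            and _sha256(outdir / name) == digest
            for name, digest in manifest.items()}


def render_multitag_svg(points: list[MultiTagPoint], path: str | Path) -> None:
    """Optional thin rendering of multi-tag points to SVG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"tag1": "#7b2d8b", "tag2": "#e6b33c", "tag3": "#3cb3b3",
              "blend": "#888844", "gray": "#bbbbbb"}
    fig, ax = plt.subplots(figsize=(7, 3))
    for pt in points:
        ax.scatter(pt.pos, pt.neglog10p, s=10 + 90 * pt.size_r2,
                   c=colors[pt.color_class], edgecolors="none", alpha=0.8)
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
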