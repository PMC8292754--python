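"""Readers, writers and the end-to-end pipeline driver.

File formats: constellations as CSV (header ``x,y,size``) or JSON with
normalization metadata; masks as single-channel 0/255 PNG; capture
histories as CSV of 0/1 with the individual id in the first column;
match reports as CSV; posterior summaries as JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image as PILImage

from .baseline import (BaselineConfig, extract_fish_mask_baseline,
                       extract_spots_baseline)
from .cjs import fit_cjs
from .errors import ParseError, ValidationError
from .groth import GrothConfig
from .histories import CaptureHistoryMatrix
from .pipeline import (ConstellationDatabase, ConstellationRecord,
                       GrothRanker, RansacRanker, correct_capture_histories,
                       decide_open_set, ensemble_decision, rank_matches)
from .prep import pca_align, spots_from_mask
from .ransac import AAConfig
from .spots import SpotSet

__all__ = [
    "read_spotset", "write_spotset",
    "read_mask", "write_mask", "read_image", "write_image",
    "read_capture_histories", "write_capture_histories",
    "PipelineConfig", "run_pipeline",
]


def write_spotset(spots: SpotSet, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "frame": list(spots.frame) if spots.frame else None,
            "normalized": bool(spots.normalized),
            "length_scale": spots.length_scale,
            "spots": [{"x": float(x), "y": float(y), "size": float(s)}
                      for (x, y), s in zip(spots.xy, spots.sizes)],
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        df = pd.DataFrame({"x": spots.xy[:, 0], "y": spots.xy[:, 1],
                           "size": spots.sizes})
        df.to_csv(path, index=False)


def read_spotset(path) -> SpotSet:
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        xy = np.array([[s["x"], s["y"]] for s in payload["spots"]],
                      dtype=float).reshape(-1, 2)
        sizes = np.array([s["size"] for s in payload["spots"]], dtype=float)
        frame = tuple(payload["frame"]) if payload.get("frame") else None
        return SpotSet(xy, sizes, frame=frame,
                       normalized=payload.get("normalized", False),
                       length_scale=payload.get("length_scale"))
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError("empty constellation file")
    header = [h.strip().lower() for h in lines[0].split(",")]
    try:
        ix, iy, isz = (header.index(c) for c in ("x", "y", "size"))
    except ValueError as exc:
        raise ParseError(f"missing column in header {header}", line=1) from exc
    xy, sizes = [], []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        try:
            xy.append((float(parts[ix]), float(parts[iy])))
            sizes.append(float(parts[isz]))
        except (ValueError, IndexError) as exc:
            raise ParseError(f"malformed row {line!r}", line=ln) from exc
    return SpotSet(np.array(xy, dtype=float).reshape(-1, 2),
                   np.array(sizes, dtype=float))


def write_mask(mask: np.ndarray, path) -> None:
    arr = (np.asarray(mask, dtype=bool) * 255).astype(np.uint8)
    PILImage.fromarray(arr, mode="L").save(path)


def read_mask(path) -> np.ndarray:
    arr = np.asarray(PILImage.open(path).convert("L"))
    return arr > 127


def write_image(image: np.ndarray, path) -> None:
    PILImage.fromarray(np.asarray(image, dtype=np.uint8)).save(path)


def read_image(path) -> np.ndarray:
    return np.asarray(PILImage.open(path).convert("RGB"))


def write_capture_histories(matrix: CaptureHistoryMatrix, path) -> None:
    df = pd.DataFrame(matrix.y,
                      columns=[f"t{t}" for t in range(matrix.n_occasions)])
    df.insert(0, "id", matrix.ids)
    df.to_csv(path, index=False)


def read_capture_histories(path) -> CaptureHistoryMatrix:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ParseError("capture-history CSV needs id plus occasions")
    ids = df.iloc[:, 0].astype(str).tolist()
    y = df.iloc[:, 1:].to_numpy()
    try:
        return CaptureHistoryMatrix(y, ids)
    except ValidationError:
        raise
    except Exception as exc:
        raise ParseError(f"invalid capture-history values: {exc}") from exc


# ---------------------------------------------------------------------------
# end-to-end pipeline over a directory of dated collections


@dataclass
class PipelineConfig:
    """Configuration of the full photograph-to-survival pipeline.

    ``input_dir`` contains one subdirectory per collection date (sorted
    lexicographically = chronologically, e.g. ``2012-06``), each holding
    PNG/JPEG photographs and optionally ``meta.csv`` with columns
    ``file,tag,fork_length``.
    """

    input_dir: str
    out_dir: str
    matcher: str = "groth"               # groth | aa | ensemble
    groth: GrothConfig = field(default_factory=GrothConfig)
    aa: AAConfig = field(default_factory=AAConfig)
    aa_threshold: float = 0.2
    seed: int = 0
    survival_samples: int = 4000
    baseline: BaselineConfig | None = None   # default: scaled per image


def _segment_record(path: Path, cfg: PipelineConfig, date, tag, fork_length):
    image = read_image(path)
    bcfg = cfg.baseline or BaselineConfig.for_image_size(max(image.shape[:2]))
    body = extract_fish_mask_baseline(image, bcfg)
    spot_mask = extract_spots_baseline(image, body, bcfg)
    raw = spots_from_mask(spot_mask)
    aligned, mask, _ = pca_align(raw, body)
    return ConstellationRecord(record_id=path.stem, date=date, spots=aligned,
                               mask=mask, observed_tag=tag,
                               fork_length=fork_length)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Segment, extract, normalize, match, decide, correct, estimate.

    Returns a report dict; all per-stage artefacts are written under
    ``cfg.out_dir``.  Any stage failure raises with the stage name; the
    artefacts of completed stages are kept on disk.
    """
    in_dir = Path(cfg.input_dir)
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    collection_dirs = sorted(
        d for d in in_dir.iterdir()
        if d.is_dir() and d.resolve() != out_dir.resolve())
    if not collection_dirs:
        raise RuntimeError("[input] no collection subdirectories found")

    groth = GrothRanker(cfg.groth)
    aa = RansacRanker(cfg.aa, threshold=cfg.aa_threshold)
    db = ConstellationDatabase()
    all_records: list[ConstellationRecord] = []
    links = []
    report_rows = []
    for date_dir in collection_dirs:
        date = date_dir.name
        meta = {}
        meta_path = date_dir / "meta.csv"
        if meta_path.exists():
            mdf = pd.read_csv(meta_path)
            for _, row in mdf.iterrows():
                meta[str(row["file"])] = (str(row["tag"]) if "tag" in row
                                          and pd.notna(row["tag"]) else None,
                                          row.get("fork_length"))
        records = []
        for img_path in sorted(date_dir.glob("*.png")) + sorted(
                date_dir.glob("*.jpg")):
            tag, fl = meta.get(img_path.name, (None, None))
            try:
                rec = _segment_record(img_path, cfg, date, tag, fl)
            except Exception as exc:
                raise RuntimeError(
                    f"[segment] {img_path.name}: {exc}") from exc
            records.append(rec)
            write_spotset(rec.spots, out_dir / f"{rec.record_id}_spots.csv")
            write_mask(rec.mask, out_dir / f"{rec.record_id}_mask.png")
        for rec in records:
            g_ranked = rank_matches(rec, db, groth, seed=cfg.seed)
            g_dec = decide_open_set(g_ranked, groth.threshold)
            if cfg.matcher == "groth":
                decision = g_dec
            else:
                a_ranked = rank_matches(rec, db, aa, seed=cfg.seed)
                a_dec = decide_open_set(a_ranked, aa.threshold)
                decision = (a_dec if cfg.matcher == "aa"
                            else ensemble_decision(g_dec, a_dec))
            if decision is not None:
                target = next(r for r in db.all_records()
                              if r.record_id == decision)
                links.append((rec, target))
            top5 = g_ranked.ids_in_order()[:5]
            report_rows.append({"query": rec.record_id, "date": date,
                                "decision": decision or "no-match",
                                "top5": ";".join(top5)})
        db.add_collection(records, date)
        all_records.extend(records)

    pd.DataFrame(report_rows).to_csv(out_dir / "match_report.csv",
                                     index=False)
    dates = [d.name for d in collection_dirs]
    corrected = correct_capture_histories(links, all_records, dates)
    write_capture_histories(corrected, out_dir / "corrected_histories.csv")
    report = {"n_records": len(all_records), "n_links": len(links),
              "n_individuals": corrected.n}
    if corrected.n_occasions >= 2 and (corrected.y.sum(axis=1) > 1).any():
        fit = fit_cjs(corrected, n_samples=max(cfg.survival_samples, 1000),
                      seed=cfg.seed)
        survival = {"phi_mean": fit.phi_mean, "p_mean": fit.p_mean,
                    "phi_hpd": list(fit.phi_hpd), "p_hpd": list(fit.p_hpd)}
        (out_dir / "survival.json").write_text(json.dumps(survival,
                                                          indent=1))
        report["survival"] = survival
    (out_dir / "report.json").write_text(json.dumps(report, indent=1))
    return report
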