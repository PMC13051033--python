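"""File formats: TPS landmark files and the pipeline's CSV schemas.

The TPS landmark dialect is the plain-text block format of the classic
morphometrics tools: each block starts with ``LM=<k>``, followed by k
whitespace-separated ``x y`` lines, then ``IMAGE=<name>`` and an optional
``ID=<n>``.  Main and semi-landmarks live in separate files (or one file each
via a ``_semi`` suffix convention).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .shape_core import AlignedShapeSet, LandmarkConfiguration
from .impression import ImpressionLabel

__all__ = [
    "read_tps",
    "write_tps",
    "read_labels_csv",
    "write_labels_csv",
    "write_aligned_csv",
]


class TpsParseError(ValueError):
    pass


def read_tps(path) -> list[dict]:
    """Parse a TPS landmark file into blocks of ``{points, image_id, id}``.

    Accepts CRLF or LF line endings and trailing blank lines; malformed blocks
    raise :class:`TpsParseError` with the offending line number.
    """
    text = Path(path).read_text()
    lines = text.replace("\r\n", "\n").replace("\r", "\n").split("\n")
    blocks: list[dict] = []
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise TpsParseError(f"{path}:{i + 1}: expected 'LM=<k>', got {line!r}")
        try:
            k = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise TpsParseError(f"{path}:{i + 1}: bad landmark count in {line!r}") from exc
        if k == 0:
            raise TpsParseError(f"{path}:{i + 1}: empty configuration (LM=0)")
        i += 1
        pts = np.empty((k, 2))
        for j in range(k):
            if i >= n:
                raise TpsParseError(f"{path}: unexpected end of file inside block")
            fields = lines[i].split()
            if len(fields) != 2:
                raise TpsParseError(
                    f"{path}:{i + 1}: expected 'x y', got {lines[i].strip()!r}"
                )
            try:
                pts[j] = [float(fields[0]), float(fields[1])]
            except ValueError as exc:
                raise TpsParseError(f"{path}:{i + 1}: non-numeric coordinate") from exc
            i += 1
        image_id = ""
        block_id = None
        while i < n and lines[i].strip() and not lines[i].strip().upper().startswith("LM="):
            tag = lines[i].strip()
            if tag.upper().startswith("IMAGE="):
                image_id = tag.split("=", 1)[1]
            elif tag.upper().startswith("ID="):
                block_id = tag.split("=", 1)[1]
            elif tag.upper().startswith("SCALE="):
                pass  # tolerated, unused
            else:
                raise TpsParseError(f"{path}:{i + 1}: unexpected line {tag!r}")
            i += 1
        blocks.append({"points": pts, "image_id": image_id, "id": block_id})
    if not blocks:
        raise TpsParseError(f"{path}: no landmark blocks found")
    return blocks


def write_tps(path, blocks: list[dict]) -> None:
    """Write landmark blocks in the TPS dialect (LF line endings)."""
    out = []
    for b in blocks:
        pts = np.asarray(b["points"], dtype=float)
        out.append(f"LM={len(pts)}")
        for x, y in pts:
            out.append(f"{x:.10g} {y:.10g}")
        out.append(f"IMAGE={b.get('image_id', '')}")
        if b.get("id") is not None:
            out.append(f"ID={b['id']}")
    Path(path).write_text("\n".join(out) + "\n")


def read_landmark_configurations(main_path, semi_path=None) -> list[LandmarkConfiguration]:
    """Read main (and optionally semi) landmark files into configurations, matched by image id."""
    main = read_tps(main_path)
    semi_by_id: dict[str, np.ndarray] = {}
    if semi_path is not None:
        for b in read_tps(semi_path):
            semi_by_id[b["image_id"]] = b["points"]
    configs = []
    for b in main:
        semi = semi_by_id.get(b["image_id"], np.empty((0, 2)))
        configs.append(
            LandmarkConfiguration(
                points_main=b["points"], points_semi=semi, image_id=b["image_id"]
            )
        )
    return configs


def write_landmark_configurations(configs: list[LandmarkConfiguration], main_path, semi_path=None):
    write_tps(main_path, [{"points": c.points_main, "image_id": c.image_id} for c in configs])
    if semi_path is not None:
        write_tps(
            semi_path, [{"points": c.points_semi, "image_id": c.image_id} for c in configs]
        )


def read_labels_csv(path) -> list[ImpressionLabel]:
    df = pd.read_csv(path)
    required = {"image_id", "trait", "rater_group", "score"}
    if not required.issubset(df.columns):
        raise ValueError(f"labels CSV must have columns {sorted(required)}")
    return [
        ImpressionLabel(
            image_id=str(r.image_id),
            trait=str(r.trait),
            rater_group=str(r.rater_group),
            score=float(r.score),
        )
        for r in df.itertuples()
    ]


def write_labels_csv(path, labels: list[ImpressionLabel]) -> None:
    pd.DataFrame(
        {
            "image_id": [l.image_id for l in labels],
            "trait": [l.trait for l in labels],
            "rater_group": [l.rater_group for l in labels],
            "score": [l.score for l in labels],
        }
    ).to_csv(path, index=False)


def write_aligned_csv(path, aligned: AlignedShapeSet) -> None:
    """One row per face: image_id, centroid_size, x1, y1, x2, y2, ..."""
    k = aligned.mean_shape.shape[0]
    cols = [f"{ax}{i + 1}" for i in range(k) for ax in ("x", "y")]
    df = pd.DataFrame(aligned.aligned.reshape(aligned.n_shapes, 2 * k), columns=cols)
    df.insert(0, "centroid_size", aligned.centroid_sizes)
    df.insert(0, "image_id", aligned.image_ids)
    df.to_csv(path, index=False)
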