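"""Landmark containers and their JSON serialization.

A specimen's landmark file holds three kinds of geometry:

* homologous landmarks — named anatomical points with one-to-one
  correspondence across specimens;
* segments — ordered polylines of non-homologous points running between two
  flanking homologous landmarks (sharp edges, curvature ridges), which are
  later resampled to equal counts at equal arc-length spacing;
* regions — closed boundary loops delimiting named surface patches
  (articular cartilage facets, the dorsal rough surface).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Segment", "LandmarkSet"]


@dataclass
class Segment:
    """Polyline between two homologous landmarks.

    ``points`` are the interior (non-homologous) samples only; the full
    polyline is start-landmark, points, end-landmark.
    """

    name: str
    start: str
    end: str
    points: np.ndarray  # (m, 3) mm

    def polyline(self, homologous: dict[str, np.ndarray]) -> np.ndarray:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 3)
        return np.vstack([homologous[self.start], pts, homologous[self.end]])


@dataclass
class LandmarkSet:
    homologous: dict[str, np.ndarray]
    segments: list[Segment] = field(default_factory=list)
    regions: dict[str, np.ndarray] = field(default_factory=dict)  # name -> (m,3) loop

    def all_points(self) -> np.ndarray:
        """Every landmark as one array: homologous, then segment interiors,
        then region-loop points, in deterministic (sorted-name) order."""
        blocks = [np.asarray(self.homologous[k], float).reshape(1, 3)
                  for k in sorted(self.homologous)]
        blocks += [np.asarray(s.points, float).reshape(-1, 3)
                   for s in sorted(self.segments, key=lambda s: s.name)]
        blocks += [np.asarray(self.regions[k], float).reshape(-1, 3)
                   for k in sorted(self.regions)]
        return np.vstack(blocks) if blocks else np.empty((0, 3))

    def transformed(self, fn) -> "LandmarkSet":
        """Apply ``fn: (n,3)->(n,3)`` to every coordinate."""
        return LandmarkSet(
            homologous={k: fn(v.reshape(1, 3))[0] for k, v in self.homologous.items()},
            segments=[Segment(s.name, s.start, s.end, fn(np.asarray(s.points).reshape(-1, 3)))
                      for s in self.segments],
            regions={k: fn(np.asarray(v).reshape(-1, 3)) for k, v in self.regions.items()},
        )

    # -- JSON dialect -----------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "homologous": [{"name": k, "xyz": np.asarray(v, float).round(9).tolist()}
                           for k, v in self.homologous.items()],
            "segments": [{"name": s.name, "start": s.start, "end": s.end,
                          "points": np.asarray(s.points, float).round(9).tolist()}
                         for s in self.segments],
            "regions": [{"name": k, "loop": np.asarray(v, float).round(9).tolist()}
                        for k, v in self.regions.items()],
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "LandmarkSet":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        return cls(
            homologous={h["name"]: np.asarray(h["xyz"], float)
                        for h in doc.get("homologous", [])},
            segments=[Segment(s["name"], s["start"], s["end"],
                              np.asarray(s["points"], float).reshape(-1, 3))
                      for s in doc.get("segments", [])],
            regions={r["name"]: np.asarray(r["loop"], float).reshape(-1, 3)
                     for r in doc.get("regions", [])},
        )
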