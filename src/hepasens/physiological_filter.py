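"""Clinical acceptance box and virtual-population assembly.

Sampling the input distributions does not guarantee physiological
outputs, so simulated subjects whose *pre-resection* outputs leave the
clinically advised ranges (MAP, CO, portal pressure, portocaval
gradient) are discarded together with their inputs.  The retained
input-output couples form the virtual population; after filtering the
pick-freeze pairing of a Saltelli design is broken, so Sobol indices on
the filtered set are only computed through the PCE surrogate.
Post-resection outputs are never filtered.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .params import INPUT_NAMES

#: outputs the clinical box constrains, and the advised ranges
DEFAULT_BOUNDS = {
    "MAP": (50.0, 130.0),    # mmHg
    "CO": (3.0, 10.0),       # L/min
    "P_pv": (3.0, 20.0),     # mmHg
    "PCG": (1.0, 14.0),      # mmHg
}


@dataclass(frozen=True)
class FilterBounds:
    """Closed acceptance intervals per clinical output (boundary values
    are retained)."""

    bounds: dict[str, tuple[float, float]]

    def __post_init__(self):
        for k, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"{k}: need min < max, got ({lo}, {hi})")

    @classmethod
    def default(cls) -> "FilterBounds":
        return cls(bounds={k: tuple(v) for k, v in DEFAULT_BOUNDS.items()})

    def to_dict(self) -> dict:
        return {k: {"min": lo, "max": hi, "units": "L/min" if k == "CO" else "mmHg"}
                for k, (lo, hi) in self.bounds.items()}

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "FilterBounds":
        doc = json.loads(Path(path).read_text())
        return cls(bounds={k: (float(v["min"]), float(v["max"])) for k, v in doc.items()})


def retention_mask(pre_outputs: pd.DataFrame, bounds: FilterBounds) -> np.ndarray:
    """True where every filtered pre-hpx output lies inside its closed
    interval; order preserved."""
    missing = [k for k in bounds.bounds if k not in pre_outputs.columns]
    if missing:
        raise ValueError(f"missing filtered output column(s): {missing}")
    mask = np.ones(len(pre_outputs), dtype=bool)
    for k, (lo, hi) in bounds.bounds.items():
        v = pre_outputs[k].to_numpy(dtype=float)
        mask &= np.isfinite(v) & (v >= lo) & (v <= hi)
    return mask


@dataclass
class VirtualPopulation:
    """Retained input-output couples with provenance."""

    inputs: pd.DataFrame
    pre: pd.DataFrame
    post: pd.DataFrame
    seed: int
    filter_version: str
    model_version: str
    n_candidates: int
    bounds: FilterBounds = field(default_factory=FilterBounds.default)

    @property
    def n_retained(self) -> int:
        return len(self.inputs)

    @property
    def retention_fraction(self) -> float:
        return self.n_retained / self.n_candidates if self.n_candidates else 0.0

    def to_frame(self) -> pd.DataFrame:
        pre = self.pre.add_suffix("_pre")
        post = self.post.add_suffix("_post")
        return pd.concat([self.inputs.reset_index(drop=True),
                          pre.reset_index(drop=True),
                          post.reset_index(drop=True)], axis=1)

    def save(self, csv_path) -> None:
        csv_path = Path(csv_path)
        self.to_frame().to_csv(csv_path, index=False, float_format="%.12g")
        sidecar = {
            "seed": self.seed,
            "filter_version": self.filter_version,
            "model_version": self.model_version,
            "n_candidates": self.n_candidates,
            "n_retained": self.n_retained,
            "retention_fraction": self.retention_fraction,
            "bounds": self.bounds.to_dict(),
        }
        csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, csv_path) -> "VirtualPopulation":
        csv_path = Path(csv_path)
        df = pd.read_csv(csv_path)
        meta = json.loads(csv_path.with_suffix(".json").read_text())
        inputs = df[[c for c in df.columns if c in INPUT_NAMES]]
        pre = df[[c for c in df.columns if c.endswith("_pre")]].rename(
            columns=lambda c: c[:-4])
        post = df[[c for c in df.columns if c.endswith("_post")]].rename(
            columns=lambda c: c[:-5])
        bounds = FilterBounds(bounds={k: (v["min"], v["max"])
                                      for k, v in meta["bounds"].items()})
        return cls(inputs=inputs, pre=pre, post=post, seed=meta["seed"],
                   filter_version=meta["filter_version"],
                   model_version=meta["model_version"],
                   n_candidates=meta["n_candidates"], bounds=bounds)


def apply_filter(inputs: pd.DataFrame, pre_outputs: pd.DataFrame,
                 post_outputs: pd.DataFrame, bounds: FilterBounds | None = None,
                 *, seed: int = 0, model_version: str = "hepasens-0.1",
                 ) -> tuple[np.ndarray, VirtualPopulation]:
    """Apply the acceptance box to pre-hpx outputs and keep the retained
    couples (inputs with both phases of outputs)."""
    bounds = bounds or FilterBounds.default()
    if not (len(inputs) == len(pre_outputs) == len(post_outputs)):
        raise ValueError("inputs and outputs must be row-aligned")
    mask = retention_mask(pre_outputs, bounds)
    digest = hashlib.blake2b(
        json.dumps(bounds.to_dict(), sort_keys=True).encode(), digest_size=6
    ).hexdigest()
    pop = VirtualPopulation(
        inputs=inputs.loc[mask].reset_index(drop=True),
        pre=pre_outputs.loc[mask].reset_index(drop=True),
        post=post_outputs.loc[mask].reset_index(drop=True),
        seed=seed, filter_version=f"box-{digest}",
        model_version=model_version, n_candidates=len(inputs), bounds=bounds)
    return mask, pop


def assemble_population(pop: VirtualPopulation, csv_path) -> Path:
    """Write the population (CSV + JSON sidecar) and return the path."""
    csv_path = Path(csv_path)
    pop.save(csv_path)
    return csv_path


def compare_distributions(pop_outputs: pd.DataFrame, ref_outputs: pd.DataFrame,
                          ) -> pd.DataFrame:
    """Median shift of every output against a reference cohort:
    |median difference|, absolute and as % of the reference median."""
    rows = []
    for col in pop_outputs.columns:
        if col not in ref_outputs.columns:
            continue
        a = pop_outputs[col].dropna()
        b = ref_outputs[col].dropna()
        if len(a) == 0 or len(b) == 0:
            raise ValueError(f"empty output set for {col!r}")
        m_pop, m_ref = float(a.median()), float(b.median())
        rows.append({
            "output": col,
            "median_pop": m_pop,
            "median_ref": m_ref,
            "abs_diff": abs(m_pop - m_ref),
            "pct_of_ref": 100.0 * abs(m_pop - m_ref) / abs(m_ref) if m_ref else np.inf,
        })
    return pd.DataFrame(rows)


#: input pairs whose joint retained region matters downstream (the
#: left-ventricular elastances with each other and with R_OO)
SUMMARY_PAIRS = (("Ea_LV", "Eb_LV"), ("Eb_LV", "R_OO"))


@dataclass(frozen=True)
class PairOccupancy:
    """Occupancy grid over a pair of inputs.

    ``counts`` holds the retained couples per cell and ``counts_rejected``
    the discarded ones.  A cell that was explored but kept nothing is an
    *excluded region*: combinations there are incompatible with
    physiological outputs.  Unexplored cells carry no evidence and are
    not excluded.
    """

    x_name: str
    y_name: str
    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray                  # (nx, ny) retained couples
    counts_rejected: np.ndarray = None  # (nx, ny) discarded couples

    def _cells(self, x, y):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        ix = np.clip(np.searchsorted(self.x_edges, x, side="right") - 1,
                     0, len(self.x_edges) - 2)
        iy = np.clip(np.searchsorted(self.y_edges, y, side="right") - 1,
                     0, len(self.y_edges) - 2)
        inside = ((x >= self.x_edges[0]) & (x <= self.x_edges[-1])
                  & (y >= self.y_edges[0]) & (y <= self.y_edges[-1]))
        return ix, iy, inside

    def contains(self, x, y) -> np.ndarray:
        """True where (x, y) falls in a cell holding retained couples."""
        ix, iy, inside = self._cells(x, y)
        return inside & (self.counts[ix, iy] > 0)

    def admissible(self, x, y) -> np.ndarray:
        """False only inside an excluded region: a cell where couples
        were simulated and every one was discarded."""
        ix, iy, inside = self._cells(x, y)
        rej = (self.counts_rejected if self.counts_rejected is not None
               else np.zeros_like(self.counts))
        excluded = (self.counts[ix, iy] == 0) & (rej[ix, iy] > 0)
        return ~(inside & excluded)


@dataclass(frozen=True)
class InputSummary:
    ranges: dict[str, tuple[float, float]]
    pairs: dict[tuple[str, str], PairOccupancy]

    def to_dict(self) -> dict:
        return {
            "ranges": {k: list(v) for k, v in self.ranges.items()},
            "pairs": {f"{a}|{b}": {
                "x_edges": p.x_edges.tolist(), "y_edges": p.y_edges.tolist(),
                "counts": p.counts.tolist(),
                "counts_rejected": (p.counts_rejected.tolist()
                                    if p.counts_rejected is not None else None),
            } for (a, b), p in self.pairs.items()},
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "InputSummary":
        pairs = {}
        for key, p in doc["pairs"].items():
            a, b = key.split("|")
            rej = p.get("counts_rejected")
            pairs[(a, b)] = PairOccupancy(
                x_name=a, y_name=b,
                x_edges=np.array(p["x_edges"]), y_edges=np.array(p["y_edges"]),
                counts=np.array(p["counts"], dtype=int),
                counts_rejected=(np.array(rej, dtype=int) if rej is not None
                                 else None))
        return cls(ranges={k: tuple(v) for k, v in doc["ranges"].items()}, pairs=pairs)


def filtered_input_summary(pop: VirtualPopulation,
                           rejected_inputs: pd.DataFrame | None = None,
                           n_bins: int = 12,
                           pairs=SUMMARY_PAIRS) -> InputSummary:
    """Per-input retained ranges plus pairwise occupancy grids for the
    input couples the filter visibly carves.

    When the discarded couples are supplied, each grid also records
    where simulations were run and rejected; cells explored without a
    single retained couple form the excluded regions used downstream to
    bound the calibration search.
    """
    if pop.n_retained == 0:
        raise ValueError("empty population")
    ranges = {n: (float(pop.inputs[n].min()), float(pop.inputs[n].max()))
              for n in pop.inputs.columns}
    grids = {}
    for a, b in pairs:
        x = pop.inputs[a].to_numpy(dtype=float)
        y = pop.inputs[b].to_numpy(dtype=float)
        if rejected_inputs is not None and len(rejected_inputs):
            xr = rejected_inputs[a].to_numpy(dtype=float)
            yr = rejected_inputs[b].to_numpy(dtype=float)
            xe = np.histogram_bin_edges(np.concatenate([x, xr]), bins=n_bins)
            ye = np.histogram_bin_edges(np.concatenate([y, yr]), bins=n_bins)
            rej, *_ = np.histogram2d(xr, yr, bins=(xe, ye))
        else:
            xe = np.histogram_bin_edges(x, bins=n_bins)
            ye = np.histogram_bin_edges(y, bins=n_bins)
            rej = np.zeros((n_bins, n_bins))
        counts, *_ = np.histogram2d(x, y, bins=(xe, ye))
        grids[(a, b)] = PairOccupancy(x_name=a, y_name=b, x_edges=xe, y_edges=ye,
                                      counts=counts.astype(int),
                                      counts_rejected=rej.astype(int))
    return InputSummary(ranges=ranges, pairs=grids)
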