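"""In-memory containers shared by all pipeline stages.

The central object is :class:`ExpressionMatrix`: a genes × arrays table
(pandas DataFrame, probe identifiers on the index, array identifiers on the
columns) plus one :class:`SampleInfo` record per array. Downstream stages
produce :class:`NormalizedMatrix`, :class:`HVResult`, :class:`ClusterTree`
and friends. All containers validate their invariants on construction.

Orientation note: matrices are genes × arrays throughout, the convention of
expression-analysis software, not the samples × features convention of
scikit-learn. Per-array operations act on columns.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DuplicateProbe, FormatError, InvalidModel

VALUE_SPACES = ("raw", "normalized_z", "log10")


@dataclass
class SampleInfo:
    """Per-array metadata: which treatment, when, which replicate."""

    array_id: str
    treatment: Optional[str] = None
    time_hours: Optional[float] = None
    replicate: Optional[int] = None

    @property
    def group(self) -> tuple:
        """Replicate-group key: arrays sharing (treatment, time) are replicates."""
        return (self.treatment, self.time_hours)


@dataclass
class ExpressionMatrix:
    """Genes × arrays expression table with per-array metadata.

    ``value_space`` declares the scale of ``values``: ``raw`` fluorescence
    (may be negative after background subtraction), ``normalized_z``
    (background-SD units) or ``log10``. NaN is forbidden in every space.
    """

    values: pd.DataFrame
    samples: list[SampleInfo] = field(default_factory=list)
    value_space: str = "raw"

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        idx = self.values.index
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise DuplicateProbe(f"duplicate probe id {dup!r}")
        if not self.samples:
            self.samples = [SampleInfo(str(c)) for c in self.values.columns]
        if len(self.samples) != self.values.shape[1]:
            raise FormatError(
                f"{len(self.samples)} sample records for "
                f"{self.values.shape[1]} array columns"
            )
        if self.value_space not in VALUE_SPACES:
            raise FormatError(f"unknown value_space {self.value_space!r}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("expression values must be numeric")
        if np.isnan(arr).any() or np.isinf(arr).any():
            raise FormatError("expression values must be finite (no NaN/inf)")

    @property
    def probe_ids(self) -> list[str]:
        return [str(p) for p in self.values.index]

    @property
    def array_ids(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_arrays(self) -> int:
        return self.values.shape[1]

    def group_labels(self) -> list[tuple]:
        """One (treatment, time) key per array, aligned with columns."""
        return [s.group for s in self.samples]

    def sample_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dataclasses.asdict(s) for s in self.samples]
        ).set_index("array_id")


@dataclass
class GeneSet:
    term_id: str
    term_name: str
    members: frozenset

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if not self.members:
            raise FormatError(f"gene set {self.term_id!r} is empty")


@dataclass
class GeneSetCollection:
    """Ordered collection of named gene sets (the GMT content model)."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.term_id for s in self.sets]
        if len(ids) != len(set(ids)):
            raise FormatError("duplicate term_id in gene set collection")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, term_id: str) -> GeneSet:
        for s in self.sets:
            if s.term_id == term_id:
                return s
        raise KeyError(term_id)


@dataclass
class BackgroundModel:
    """Per-array background Gaussian plus cross-array affine alignment.

    ``per_array`` maps array_id -> (mean, sd) of the low-expression mode;
    ``alignment`` maps array_id -> (slope, intercept) of the robust
    regression onto the reference; an aligned value is
    (value - intercept) / slope on the log10 scale.
    """

    per_array: Mapping[str, tuple[float, float]]
    alignment: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    reference_id: str = "median-pseudo-array"

    def __post_init__(self) -> None:
        for aid, (_, sd) in self.per_array.items():
            if not sd > 0:
                raise InvalidModel(f"array {aid!r}: sd must be > 0, got {sd}")
        for aid, (slope, _) in self.alignment.items():
            if not np.isfinite(slope):
                raise InvalidModel(f"array {aid!r}: non-finite slope")


@dataclass
class NormalizedMatrix:
    """Log10-scale expression with its pre-floor expression mask.

    ``expressed`` is True where the pre-floor z-score reached
    ``z_threshold`` (default 3 background SDs); the mask is computed before
    flooring and before alignment and never changes afterwards.
    """

    log_values: pd.DataFrame
    expressed: pd.DataFrame
    z_threshold: float = 3.0
    floor_z: float = 1.0
    model: Optional[BackgroundModel] = None

    def __post_init__(self) -> None:
        if self.log_values.shape != self.expressed.shape:
            raise FormatError("log_values and expressed mask shapes differ")
        if not self.z_threshold > self.floor_z > 0:
            raise FormatError("need z_threshold > floor_z > 0")

    @property
    def log_threshold(self) -> float:
        return float(np.log10(self.z_threshold))

    def expressed_genes(self, min_arrays: int = 1) -> pd.Index:
        """Genes expressed in at least ``min_arrays`` arrays."""
        return self.log_values.index[
            self.expressed.to_numpy().sum(axis=1) >= min_arrays
        ]


@dataclass
class ReferenceGroup:
    """Low-variability reference genes and their pooled technical variance."""

    member_probe_ids: list[str]
    pooled_variance: float
    pooled_df: int
    iterations_to_converge: int

    def __post_init__(self) -> None:
        if not self.pooled_variance > 0:
            raise InvalidModel("pooled reference variance must be > 0")


@dataclass
class HVResult:
    """Per-gene hypervariability statistics over the expressed genes.

    ``table`` columns: variance (about the gene's grand mean), df, F
    (ratio to the pooled reference variance), p (upper tail), cutoff,
    hv_flag, loo_dropped, suspect_sample.
    """

    table: pd.DataFrame
    n_expressed: int
    p_cutoff: float
    reference: ReferenceGroup

    def __post_init__(self) -> None:
        t = self.table
        bad = t["hv_flag"] & (~(t["p"] < self.p_cutoff) | t["loo_dropped"])
        if bad.any():
            raise InvalidModel("hv_flag set for a gene failing p or loo filter")

    @property
    def hv_probes(self) -> list[str]:
        return list(self.table.index[self.table["hv_flag"]])


@dataclass
class ClusterTree:
    """Agglomerative dendrogram over HV genes.

    ``merges`` lists (node_a, node_b, distance, new_node_id) in merge order;
    leaves are numbered 0..n-1 in ``leaf_ids`` order, internal nodes from n.
    """

    merges: list[tuple[int, int, float, int]]
    leaf_ids: list[str]

    def __post_init__(self) -> None:
        n = len(self.leaf_ids)
        if n >= 2 and len(self.merges) != n - 1:
            raise InvalidModel(f"{n} leaves require {n - 1} merges")

    def _children(self) -> dict[int, tuple[int, int]]:
        return {m[3]: (m[0], m[1]) for m in self.merges}

    def _heights(self) -> dict[int, float]:
        h = {i: 0.0 for i in range(len(self.leaf_ids))}
        for a, b, d, new in self.merges:
            h[new] = float(d)
        return h

    def leaf_order(self) -> list[str]:
        """Display order: larger subtree first at each merge, ties broken by
        the smallest leaf id contained in the subtree."""
        children = self._children()

        def leaves(node: int) -> list[int]:
            if node < len(self.leaf_ids):
                return [node]
            a, b = children[node]
            la, lb = leaves(a), leaves(b)
            ka = (-len(la), min(self.leaf_ids[i] for i in la))
            kb = (-len(lb), min(self.leaf_ids[i] for i in lb))
            return la + lb if ka <= kb else lb + la

        if not self.merges:
            return list(self.leaf_ids)
        root = self.merges[-1][3]
        return [self.leaf_ids[i] for i in leaves(root)]

    def to_newick(self) -> str:
        """Newick string; each merge distance is split equally between the
        two children, so a pair merging at d gets branch lengths d/2."""
        children = self._children()
        heights = self._heights()

        def render(node: int, parent_h: float) -> str:
            bl = (parent_h - heights[node]) / 2.0
            if node < len(self.leaf_ids):
                return f"{self.leaf_ids[node]}:{bl:.10g}"
            a, b = children[node]
            h = heights[node]
            return f"({render(a, h)},{render(b, h)}):{bl:.10g}"

        if len(self.leaf_ids) == 1:
            return f"{self.leaf_ids[0]}:0;"
        root = self.merges[-1][3]
        h = heights[root]
        a, b = children[root]
        return f"({render(a, h)},{render(b, h)});"


@dataclass
class SetPartition:
    """Common / condition-specific split of two HV gene sets."""

    common: frozenset
    only_a: frozenset
    only_b: frozenset
    label_a: str = "a"
    label_b: str = "b"

    def __post_init__(self) -> None:
        if self.common & self.only_a or self.common & self.only_b or (
            self.only_a & self.only_b
        ):
            raise InvalidModel("partition sets must be pairwise disjoint")

    def set_a(self) -> frozenset:
        return self.common | self.only_a

    def set_b(self) -> frozenset:
        return self.common | self.only_b


@dataclass
class ViabilitySeries:
    """XTT plate summarized as replicate absorbances per dilution.

    Dilution factors are the denominators of v/v dilutions: 1100.0 means a
    1:1,100 dilution; larger factor = more dilute = lower dose.
    """

    dilution_factors: Sequence[float]
    absorbance_t0: Mapping[float, Sequence[float]]
    absorbance_t24: Mapping[float, Sequence[float]]
    control_t0: Sequence[float]
    control_t24: Sequence[float]

    def __post_init__(self) -> None:
        d = list(self.dilution_factors)
        if any(x <= 0 for x in d):
            raise FormatError("dilution factors must be positive")
        if len(set(d)) != len(d):
            raise FormatError("dilution factors must be distinct")
        for df_ in d:
            if not list(self.absorbance_t0[df_]) or not list(self.absorbance_t24[df_]):
                raise FormatError("replicate lists must be non-empty")


@dataclass
class PcrQuartet:
    """The four cycle thresholds of a Livak relative quantification."""

    ct_target_treated: float
    ct_reference_treated: float
    ct_target_control: float
    ct_reference_control: float

    def __post_init__(self) -> None:
        vals = dataclasses.astuple(self)
        if not all(np.isfinite(v) for v in vals):
            raise FormatError("Ct values must be finite")
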