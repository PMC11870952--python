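"""Domain types shared across the pipeline.

Every record type validates its own invariants on construction via
``validate()``; readers call this per row so malformed data never enters the
pipeline silently.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError


class Season(str, enum.Enum):
    """The two hydrological seasons of a tropical floodplain survey."""

    RAINY = "rainy"
    DRY = "dry"

    @classmethod
    def parse(cls, token: str) -> "Season":
        try:
            return cls(str(token).strip().lower())
        except ValueError:
            raise ValidationError(
                f"unknown season token {token!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


#: The ten liver lesion categories scored in the histology screen:
#: steatosis, lymphocytic infiltrates, melanomacrophage inflammation,
#: vessel fibrosis, hepatocyte hypertrophy, nuclear hypertrophy, necrosis,
#: apoptosis, hepatic congestion, blood congestion.
LESION_CATEGORIES: tuple[str, ...] = (
    "ST", "LY", "MM", "FB", "HH", "NH", "NC", "AP", "HC", "BC",
)


@dataclass
class FishSpecimen:
    """One sampled fish.

    Units: total length in cm, total and liver weight in g, muscle total
    mercury in µg/g wet weight. ``liver_weight_g`` and ``thg_ugg`` are
    optional (None, never 0, when unmeasured).
    """

    id: str
    species: str
    season: Season
    length_cm: float
    weight_g: float
    parasite_count: int
    trophic_level: float
    liver_weight_g: float | None = None
    thg_ugg: float | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.season, Season):
            self.season = Season.parse(self.season)
        self.validate()

    def validate(self) -> None:
        if not (self.length_cm > 0):
            raise ValidationError(f"specimen {self.id}: length_cm must be > 0")
        if not (self.weight_g > 0):
            raise ValidationError(f"specimen {self.id}: weight_g must be > 0")
        if self.parasite_count < 0 or self.parasite_count != int(self.parasite_count):
            raise ValidationError(
                f"specimen {self.id}: parasite_count must be a nonnegative integer"
            )
        if self.liver_weight_g is not None:
            if self.liver_weight_g < 0:
                raise ValidationError(
                    f"specimen {self.id}: liver_weight_g must be >= 0"
                )
            if self.liver_weight_g > self.weight_g:
                raise ValidationError(
                    f"specimen {self.id}: liver weight "
                    f"{self.liver_weight_g} g exceeds body weight {self.weight_g} g"
                )
        if self.thg_ugg is not None and self.thg_ugg < 0:
            raise ValidationError(f"specimen {self.id}: thg_ugg must be >= 0")
        if not (2.0 <= self.trophic_level <= 5.0):
            raise ValidationError(
                f"specimen {self.id}: trophic_level {self.trophic_level} "
                "outside [2.0, 5.0]"
            )


@dataclass
class SpeciesSeasonProfile:
    """Calibration targets for one species x season stratum.

    Means are paired with standard errors as surveys report them; the
    generator recovers the sample sd as se * sqrt(n). ``mean_intensity`` is
    parasites per infected fish; ``dispersion_k`` is the negative-binomial
    shape used only when simulating counts.
    """

    species: str
    season: Season
    trophic_level: float
    n: int
    mean_length_cm: float
    se_length_cm: float
    mean_weight_g: float
    se_weight_g: float
    mean_cf: float
    se_cf: float
    mean_hsi: float
    se_hsi: float
    mean_thg_ugg: float
    se_thg_ugg: float
    prevalence: float
    mean_intensity: float
    dispersion_k: float = 1.0

    def __post_init__(self) -> None:
        if not isinstance(self.season, Season):
            self.season = Season.parse(self.season)
        if self.n < 1:
            raise ValidationError(f"{self.species}/{self.season}: n must be >= 1")
        if not (0.0 <= self.prevalence <= 1.0):
            raise ValidationError(
                f"{self.species}/{self.season}: prevalence outside [0, 1]"
            )
        if self.prevalence > 0 and self.mean_intensity < 1:
            raise ValidationError(
                f"{self.species}/{self.season}: mean intensity must be >= 1 "
                "when prevalence > 0"
            )
        for name in ("se_length_cm", "se_weight_g", "se_cf", "se_hsi", "se_thg_ugg"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{self.species}/{self.season}: {name} < 0")
        if self.dispersion_k <= 0:
            raise ValidationError(
                f"{self.species}/{self.season}: dispersion_k must be > 0"
            )

    @property
    def mean_abundance(self) -> float:
        return self.prevalence * self.mean_intensity


@dataclass
class ParasitologySummary:
    """Prevalence / mean abundance / mean intensity for one stratum.

    Follows the standard quantitative-parasitology conventions: prevalence is
    infected/examined, abundance averages over all examined hosts, intensity
    only over infected hosts (undefined — ``None`` — when none are infected).
    """

    species: str  # or "overall"
    season: str   # season value or "both"
    n_examined: int
    n_infected: int
    total_parasites: int
    se_abundance: float | None = None

    def __post_init__(self) -> None:
        if self.n_examined < 1:
            raise ValidationError("n_examined must be >= 1")
        if not (0 <= self.n_infected <= self.n_examined):
            raise ValidationError("n_infected outside [0, n_examined]")
        if self.n_infected > 0 and self.total_parasites < self.n_infected:
            raise ValidationError("total_parasites < n_infected")

    @property
    def prevalence(self) -> float:
        return self.n_infected / self.n_examined

    @property
    def mean_abundance(self) -> float:
        return self.total_parasites / self.n_examined

    @property
    def mean_intensity(self) -> float | None:
        if self.n_infected == 0:
            return None
        return self.total_parasites / self.n_infected


@dataclass
class ConsumerProfile:
    """A consumer scenario: standard meal size (g) and body weight (kg)."""

    name: str
    meal_size_g: float
    body_weight_kg: float

    def __post_init__(self) -> None:
        if self.meal_size_g <= 0 or self.body_weight_kg <= 0:
            raise ValidationError(
                f"profile {self.name}: meal size and body weight must be positive"
            )


@dataclass
class RiskResult:
    """Mercury exposure and consumption-limit result for one stratum x scenario."""

    species: str
    season: str
    profile: str
    thg_ugg: float
    c_mehg_ugg: float
    edi_ugkgday: float
    hq: float
    crmw_raw: float
    crmw_meals: int
    unrestricted: bool
    verdict: str  # "risk" iff hq > 1 else "minimal"


@dataclass
class HistoProfile:
    """Semi-quantitative liver lesion scores (0-3) for one specimen."""

    specimen_id: str
    species: str
    scores: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in LESION_CATEGORIES if c not in self.scores]
        if missing:
            raise ValidationError(
                f"profile {self.specimen_id}: missing lesion categories {missing}"
            )
        for cat, s in self.scores.items():
            if cat not in LESION_CATEGORIES:
                raise ValidationError(
                    f"profile {self.specimen_id}: unknown category {cat!r}"
                )
            if s not in (0, 1, 2, 3):
                raise ValidationError(
                    f"profile {self.specimen_id}: score {s!r} for {cat} "
                    "not in {0, 1, 2, 3}"
                )

    def vector(self) -> np.ndarray:
        return np.array([self.scores[c] for c in LESION_CATEGORIES], dtype=float)


@dataclass
class StatTestResult:
    """Outcome of one assumption-gated hypothesis test."""

    test_name: str
    statistic: float
    p_value: float
    alpha: float = 0.05
    decision_path: str = ""

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass
class ModelFit:
    """One ordinary-least-squares fit along a backward-selection path."""

    terms: tuple[str, ...]            # predictors, intercept implicit
    coefficients: dict[str, float]    # includes "Intercept"
    std_errors: dict[str, float]
    p_values: dict[str, float]
    aic: float
    adjusted_r2: float
    n: int


class AlignedSequences:
    """An immutable multiple alignment over the {A, C, G, T, N, -} alphabet."""

    ALPHABET = frozenset("ACGTN-")

    def __init__(self, records: list[tuple[str, str]]):
        if not records:
            raise ValidationError("alignment has no sequences")
        ids = [r[0] for r in records]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sequence ids in alignment")
        seqs = [r[1].upper() for r in records]
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            from .errors import AlignmentError

            raise AlignmentError(
                f"sequences have unequal lengths {sorted(lengths)}; "
                "input must be pre-aligned"
            )
        for sid, seq in zip(ids, seqs):
            for pos, ch in enumerate(seq):
                if ch not in self.ALPHABET:
                    raise ValidationError(
                        f"sequence {sid!r}: illegal character {ch!r} at "
                        f"position {pos + 1}"
                    )
        self.records: list[tuple[str, str]] = list(zip(ids, seqs))
        self.length: int = lengths.pop()

    @property
    def ids(self) -> list[str]:
        return [sid for sid, _ in self.records]

    def matrix(self) -> np.ndarray:
        """Alignment as an (n_seq, length) array of single characters."""
        return np.array([list(s) for _, s in self.records])

    def __len__(self) -> int:
        return len(self.records)


class DistanceMatrix:
    """A labelled symmetric distance matrix with zero diagonal."""

    def __init__(self, labels: list[str], d: np.ndarray):
        d = np.asarray(d, dtype=float)
        if d.shape != (len(labels), len(labels)):
            raise ValidationError("distance matrix shape does not match labels")
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate labels in distance matrix")
        if not np.all(np.isfinite(d)):
            raise ValidationError("distance matrix has non-finite entries")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal is not zero")
        if np.any(d < -1e-12):
            raise ValidationError("distance matrix has negative entries")
        self.labels = list(labels)
        self.d = np.clip((d + d.T) / 2.0, 0.0, None)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.d[i, j])


class TreeNode:
    """A rooted tree node used for both NJ outputs and simulation inputs.

    Unrooted NJ trees are represented with a trifurcating root. ``support``
    holds an integer bootstrap percentage on internal nodes, rendered as the
    internal-node label in newick output.
    """

    def __init__(
        self,
        name: str | None = None,
        length: float | None = None,
        children: list["TreeNode"] | None = None,
        support: int | None = None,
    ):
        self.name = name
        self.length = length
        self.children = children or []
        self.support = support

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.leaves()]

    def newick(self) -> str:
        """Serialize as newick; bootstrap supports become internal labels."""
        return self._newick_node() + ";"

    def _newick_node(self) -> str:
        if self.is_leaf:
            if self.name is None:
                raise ValidationError("cannot serialize a tree with unnamed leaves")
            label = str(self.name)
        else:
            inner = ",".join(c._newick_node() for c in self.children)
            label = f"({inner})"
            if self.support is not None:
                label += str(int(self.support))
            elif self.name:
                label += str(self.name)
        if self.length is not None:
            label += f":{_fmt_len(self.length)}"
        return label

    def path_lengths(self) -> dict[tuple[str, str], float]:
        """Leaf-to-leaf path lengths (keys sorted pairs); treats root as hub."""
        dists: dict[str, float] = {}

        def down(node: TreeNode, acc: float, store: dict[str, float]) -> None:
            acc += node.length or 0.0
            if node.is_leaf:
                store[node.name] = acc
            for c in node.children:
                down(c, acc, store)

        # distance from every node-rooted subtree; simple O(n^2) walk
        out: dict[tuple[str, str], float] = {}

        def collect(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: node.length or 0.0}
            per_child = []
            for c in node.children:
                sub = collect(c)
                per_child.append(sub)
            for i in range(len(per_child)):
                for j in range(i + 1, len(per_child)):
                    for a, da in per_child[i].items():
                        for b, db in per_child[j].items():
                            key = (a, b) if a < b else (b, a)
                            out[key] = da + db
            merged = {}
            for sub in per_child:
                for a, da in sub.items():
                    merged[a] = da + (node.length or 0.0)
            return merged

        collect(self)
        return out


def _fmt_len(x: float) -> str:
    if x == int(x) and abs(x) < 1e15:
        return f"{x:.1f}"
    return f"{x:.6g}"


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, as canonical leaf sets.

    Each internal edge splits the leaves in two; the side not containing the
    alphabetically first leaf is the canonical representative.
    """
    all_leaves = frozenset(tree.leaf_names())
    anchor = min(all_leaves)
    splits: set[frozenset[str]] = set()

    def walk(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(walk(c) for c in node.children))
        if node is not tree and 1 < len(below) < len(all_leaves) - 1:
            side = below if anchor not in below else all_leaves - below
            splits.add(side)
        return below

    walk(tree)
    return splits


def is_number(x) -> bool:
    try:
        return math.isfinite(float(x))
    except (TypeError, ValueError):
        return False
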