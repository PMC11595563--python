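"""Time-calibrated trees: ultrametricity checks, node and stem ages,
mean divergence times and lineage-through-time counts.

Ages are measured backward in Myr from the tips, which sit at age 0; the
root is the oldest node.  The divergence time of a species is its *stem*
age — the age of the node where its terminal branch (or, for a clade, the
clade's ancestral branch) attaches to the rest of the tree.
"""

from __future__ import annotations

import io
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "TimeTree", "StemAgeTable", "read_tree", "mean_divergence_time",
]


def _parse(**kw) -> dendropy.Tree:
    """Parse a tree, normalizing dendropy's reader errors to ValueError."""
    try:
        return dendropy.Tree.get(rooting="default-rooted", **kw)
    except dendropy.dataio.newickreader.NewickReader.\
            NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate tip labels: {exc}") from exc
    except Exception as exc:
        raise ValueError(f"malformed tree: {exc}") from exc


class TimeTree:
    """A rooted ultrametric chronogram.

    Wraps a :class:`dendropy.Tree`, caches node ages, and exposes the
    age queries the downstream analyses need.  Branch lengths are Myr.
    """

    def __init__(self, dtree: dendropy.Tree, *,
                 require_ultrametric: bool = True,
                 ultrametric_rtol: float = 1e-6):
        self.dtree = dtree
        self.dtree.is_rooted = True
        labels = [lf.taxon.label for lf in dtree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        self.tip_labels = labels
        # depth of every node from the root
        self._depth: dict = {}
        for nd in dtree.preorder_node_iter():
            parent_depth = self._depth.get(nd.parent_node, 0.0)
            edge = nd.edge.length or 0.0
            if edge < 0:
                raise ValueError("negative branch length")
            self._depth[nd] = parent_depth + edge
        tip_depths = np.array([self._depth[lf]
                               for lf in dtree.leaf_node_iter()])
        self.root_age = float(tip_depths.max())
        if require_ultrametric and self.root_age > 0:
            spread = tip_depths.max() - tip_depths.min()
            if spread > ultrametric_rtol * self.root_age:
                raise ValueError(
                    f"tree is not ultrametric: tip depths span {spread:g} "
                    f"(> {ultrametric_rtol:g} x root age {self.root_age:g})")
        self._leaf_by_label = {lf.taxon.label: lf
                               for lf in dtree.leaf_node_iter()}

    # -- construction -------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str, **kw) -> "TimeTree":
        dtree = _parse(data=newick, schema="newick")
        return cls(dtree, **kw)

    def as_newick(self) -> str:
        return self.dtree.as_string(schema="newick",
                                    suppress_rooting=True).strip()

    def write(self, path, schema: str = "newick") -> None:
        self.dtree.write(path=str(path), schema=schema)

    # -- ages ---------------------------------------------------------------
    def age(self, node) -> float:
        """Age of a node (root age minus depth; tips at ~0)."""
        return self.root_age - self._depth[node]

    def node_ages(self) -> list[float]:
        """Ages of all internal nodes, unsorted."""
        return [self.age(nd) for nd in self.dtree.preorder_internal_node_iter()]

    def stem_age(self, tip: str) -> float:
        """Age of the tip's parent node — equivalently its terminal branch
        length on an ultrametric tree."""
        leaf = self._leaf_by_label.get(tip)
        if leaf is None:
            raise KeyError(f"unknown tip {tip!r}")
        return self.age(leaf.parent_node)

    def clade_stem_age(self, tips: Iterable[str]) -> float:
        """Age of the parent of the MRCA of *tips*; requires monophyly."""
        tips = set(tips)
        if not tips:
            raise ValueError("empty tip set")
        unknown = tips - set(self.tip_labels)
        if unknown:
            raise KeyError(f"unknown tips: {sorted(unknown)}")
        mrca = self.mrca(tips)
        clade_tips = {lf.taxon.label for lf in mrca.leaf_iter()}
        if clade_tips != tips:
            raise ValueError(
                f"tip set is not monophyletic; its MRCA also spans "
                f"{sorted(clade_tips - tips)}")
        if mrca.parent_node is None:
            raise ValueError("root clade: the full tip set has no stem "
                             "(the root has no parent)")
        return self.age(mrca.parent_node)

    def mrca(self, tips: Iterable[str]):
        taxa = [self._leaf_by_label[t].taxon for t in tips]
        return self.dtree.mrca(taxa=taxa)

    # -- descriptive --------------------------------------------------------
    def ltt(self) -> list[tuple[float, int]]:
        """Lineage-through-time step function from the root toward the
        present: ``[(age, count), ...]`` with count lineages alive on the
        interval from that age down to the next entry (or 0).  Starts at 2
        for a rooted bifurcating root and ends at the tip count."""
        internal_ages = sorted(
            (self.age(nd) for nd in self.dtree.preorder_internal_node_iter()),
            reverse=True)
        steps: list[tuple[float, int]] = []
        count = 1
        for a in internal_ages:
            count += 1
            if steps and np.isclose(steps[-1][0], a):
                steps[-1] = (steps[-1][0], count)
            else:
                steps.append((a, count))
        return steps

    def rescale(self, target_root_age: float) -> "TimeTree":
        """Return a copy with branch lengths scaled so the root sits at
        *target_root_age* Myr."""
        if self.root_age <= 0:
            raise ValueError("cannot rescale a zero-depth tree")
        factor = target_root_age / self.root_age
        clone = self.dtree.clone(depth=1)
        for edge in clone.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= factor
        return TimeTree(clone)


def read_tree(path, format: str = "newick", *,
              allow_nonultrametric: bool = False) -> TimeTree:
    """Read a chronogram from a newick or NEXUS file.

    Rejects duplicate tip labels always, and non-ultrametric trees unless
    *allow_nonultrametric* is set.
    """
    if format not in ("newick", "nexus"):
        raise ValueError(f"unsupported tree format {format!r}")
    dtree = _parse(path=str(path), schema=format)
    return TimeTree(dtree, require_ultrametric=not allow_nonultrametric)


class StemAgeTable:
    """Species -> stem age (Myr) lookup.

    When a species is represented by several collections (tips) on the
    tree, its stem age is the age of the parent of the MRCA of those tips;
    a single tip contributes its own stem age.
    """

    def __init__(self, ages: Mapping[str, float]):
        bad = [s for s, a in ages.items() if not a > 0]
        if bad:
            raise ValueError(f"non-positive stem ages for {bad}")
        self.ages = dict(ages)

    def __getitem__(self, species: str) -> float:
        return self.ages[species]

    def __contains__(self, species: str) -> bool:
        return species in self.ages

    def __len__(self) -> int:
        return len(self.ages)

    @classmethod
    def from_tree(cls, tree: TimeTree,
                  species_of: Mapping[str, str] | None = None
                  ) -> "StemAgeTable":
        """Build the table from a chronogram.

        *species_of* maps tip label -> species name (defaults to identity,
        one tip per species).
        """
        if species_of is None:
            species_of = {t: t for t in tree.tip_labels}
        groups: dict[str, list[str]] = {}
        for tip in tree.tip_labels:
            sp = species_of.get(tip)
            if sp is not None:
                groups.setdefault(sp, []).append(tip)
        ages = {}
        for sp, tips in groups.items():
            if len(tips) == 1:
                ages[sp] = tree.stem_age(tips[0])
            else:
                mrca = tree.mrca(tips)
                if mrca.parent_node is None:
                    raise ValueError(f"species {sp!r} spans the whole tree")
                ages[sp] = tree.age(mrca.parent_node)
        return cls(ages)

    def to_csv(self, path) -> None:
        pd.DataFrame(sorted(self.ages.items()),
                     columns=["species", "stem_age"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "StemAgeTable":
        df = pd.read_csv(path)
        return cls(dict(zip(df["species"], df["stem_age"])))


def mean_divergence_time(species: Iterable[str], table: StemAgeTable) -> float:
    """Arithmetic mean stem age of a set of species (duplicates collapse)."""
    sps = set(species)
    if not sps:
        raise ValueError("empty species set")
    missing = [s for s in sps if s not in table]
    if missing:
        raise KeyError(f"species missing from stem-age table: "
                       f"{sorted(missing)}")
    return float(np.mean([table[s] for s in sps]))
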