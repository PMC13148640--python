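"""Extant Phylogenetic Bracket (EPB) muscle reconstruction.

Soft tissues of a fossil are inferred from the minimal extant clade
bracketing it: muscle-attachment characters are scored across living and
fossil saurians, ancestral states are reconstructed under maximum parsimony
(unordered, unweighted), and each reconstructed attachment is assigned a
Witmer inference level -- I (unequivocal bracket agreement) or II
(equivocal), with a prime mark when the fossil itself shows no clear
osteological correlate of the attachment.

Parsimony here is unit-cost (Fitch-style) but implemented as a two-pass
dynamic programme over arbitrary rooted trees (polytomies included): a
post-order pass accumulates subtree costs per state, a pre-order rerooting
pass adds the cost of the rest of the tree, and the MPR set at a node is
the set of states achieving the global minimum change count. Ambiguity is
reported as state *sets*, never resolved arbitrarily -- only unambiguous
(singleton) reconstructions are used for level-I/II assignment.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

MISSING = "?"
INAPPLICABLE = "-"


# ---------------------------------------------------------------------------
# Tree and matrix parsing
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> dendropy.Tree:
    """Parse a rooted Newick tree; duplicate tip labels are an error."""
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 suppress_internal_node_taxa=True)
    except Exception as e:
        if "Duplicate" in str(e) or "Multiple occurrences" in str(e):
            raise ValueError(f"duplicate tip labels: {e}") from e
        raise
    return tree


def to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick").strip()


@dataclass
class CharacterMatrix:
    """Taxa x characters of small integer state codes.

    ``data`` maps taxon -> list of cell strings; a cell is a digit, "?"
    (missing: any state) or "-" (inapplicable: treated as missing for
    optimisation, flagged separately in reports).
    """

    data: dict
    n_chars: int
    char_labels: list = field(default_factory=list)

    def __post_init__(self):
        for taxon, row in self.data.items():
            if len(row) != self.n_chars:
                raise ValueError(
                    f"taxon {taxon!r}: {len(row)} cells, expected {self.n_chars}")
        if not self.char_labels:
            self.char_labels = [f"char_{i + 1}" for i in range(self.n_chars)]

    @property
    def taxa(self):
        return list(self.data)

    def states_for(self, char_index: int) -> set:
        obs = set()
        for row in self.data.values():
            cell = row[char_index]
            if cell not in (MISSING, INAPPLICABLE):
                obs.add(int(cell))
        return obs

    def cell_state_set(self, taxon: str, char_index: int, all_states: set) -> set:
        cell = self.data[taxon][char_index]
        if cell in (MISSING, INAPPLICABLE):
            return set(all_states)
        return {int(cell)}


def parse_character_matrix(source) -> CharacterMatrix:
    """Read a character matrix from CSV text/path or a NEXUS subset.

    CSV: first column taxon names, remaining columns characters. NEXUS: a
    CHARACTERS (or DATA) block with DIMENSIONS and a MATRIX of
    whitespace-separated taxon / state-string rows.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
        if "\n" not in text and not text.lstrip().startswith("#"):
            with open(text) as fh:
                text = fh.read()
    if text.lstrip().upper().startswith("#NEXUS"):
        return _parse_nexus_matrix(text)
    df = pd.read_csv(io.StringIO(text), dtype=str)
    taxa_col = df.columns[0]
    data = {row[taxa_col]: [str(v).strip() for v in row[1:]]
            for _, row in df.iterrows()}
    return CharacterMatrix(data, n_chars=df.shape[1] - 1,
                           char_labels=list(df.columns[1:]))


def _parse_nexus_matrix(text: str) -> CharacterMatrix:
    m = re.search(r"DIMENSIONS[^;]*NCHAR\s*=\s*(\d+)", text, re.I)
    if not m:
        raise ValueError("NEXUS: missing DIMENSIONS NCHAR")
    nchar = int(m.group(1))
    mm = re.search(r"MATRIX(.*?);", text, re.S | re.I)
    if not mm:
        raise ValueError("NEXUS: missing MATRIX block")
    data = {}
    for line in mm.group(1).strip().splitlines():
        line = line.strip()
        if not line or line.startswith("["):
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise ValueError(f"NEXUS: malformed matrix row {line!r}")
        taxon, states = parts[0].strip("'\""), parts[1].replace(" ", "")
        data[taxon] = list(states)
    return CharacterMatrix(data, n_chars=nchar)


# ---------------------------------------------------------------------------
# Parsimony ancestral states
# ---------------------------------------------------------------------------

@dataclass
class AncestralStateMap:
    """Per-character MPR state sets at internal nodes plus minimum change
    counts. Node keys are dendropy node ids; the root is ``root_id``."""

    node_states: dict  # char_index -> {node_id: frozenset of states}
    change_counts: dict  # char_index -> int
    skipped_chars: list
    root_id: int

    def root_states(self, char_index: int) -> frozenset:
        return self.node_states[char_index][self.root_id]


def _unit_cost_mpr(tree, tip_state_sets, states):
    """MPR sets and min change count for one unordered character."""
    INF = float("inf")
    states = sorted(states)
    idx = {s: i for i, s in enumerate(states)}
    k = len(states)
    down = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            allowed = tip_state_sets[node.taxon.label]
            down[id(node)] = np.array(
                [0.0 if s in allowed else INF for s in states])
        else:
            cost = np.zeros(k)
            for ch in node.child_nodes():
                c = down[id(ch)]
                best = c.min()
                # min over t of c[t] + [s != t]  ==  min(c[s], best + 1)
                cost += np.minimum(c, best + 1.0)
            down[id(node)] = cost
    root = tree.seed_node
    total = down[id(root)].min()
    up = {id(root): np.zeros(k)}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        children = node.child_nodes()
        contrib = [np.minimum(down[id(c)], down[id(c)].min() + 1.0)
                   for c in children]
        total_contrib = np.sum(contrib, axis=0)
        for c, own in zip(children, contrib):
            rest = up[id(node)] + total_contrib - own  # cost excluding c's subtree
            # up[c][s] = min_t rest[t] + [t != s]
            up[id(c)] = np.minimum(rest, rest.min() + 1.0)
    mpr = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        score = down[id(node)] + up[id(node)]
        mpr[id(node)] = frozenset(
            s for s, i in idx.items() if score[i] <= total + 1e-9)
    return mpr, int(total)


def fitch_optimize(tree: dendropy.Tree, matrix: CharacterMatrix) -> AncestralStateMap:
    """Maximum-parsimony (unordered, unweighted) ancestral-state sets and
    minimum change counts for every character.

    Missing ("?") and inapplicable ("-") cells allow any observed state.
    All-missing characters are flagged and skipped. The change count is the
    Fitch minimum; node sets are full MPR sets (states attained by at least
    one most-parsimonious assignment).
    """
    tip_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing_taxa = set(matrix.taxa) - tip_labels
    absent_taxa = tip_labels - set(matrix.taxa)
    if absent_taxa:
        raise ValueError(f"tree tips not in matrix: {sorted(absent_taxa)}")
    node_states, change_counts, skipped = {}, {}, []
    for ci in range(matrix.n_chars):
        observed = matrix.states_for(ci)
        if not observed:
            skipped.append(ci)
            continue
        tip_sets = {t: matrix.cell_state_set(t, ci, observed) for t in tip_labels}
        mpr, total = _unit_cost_mpr(tree, tip_sets, observed)
        node_states[ci] = mpr
        change_counts[ci] = total
    return AncestralStateMap(node_states, change_counts, skipped,
                             root_id=id(tree.seed_node))


def brute_force_min_changes(tree: dendropy.Tree, tip_state_sets: dict,
                            states) -> tuple:
    """Exhaustive-enumeration oracle: try every assignment of states to
    internal nodes (and to ambiguous tips) and count edge changes. Returns
    (min_changes, mpr_sets_by_node_id). Only feasible for tiny trees."""
    from itertools import product

    states = sorted(states)
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    leaves = list(tree.leaf_node_iter())
    leaf_choices = [sorted(tip_state_sets[l.taxon.label]) for l in leaves]
    best = float("inf")
    winners = {id(n): set() for n in internals}
    for internal_assign in product(states, repeat=len(internals)):
        assign = {id(n): s for n, s in zip(internals, internal_assign)}
        # greedy best tip choice given fixed internals (tips only touch parent)
        cost = 0
        for l, choices in zip(leaves, leaf_choices):
            p = assign[id(l.parent_node)]
            cost += min(1 if c != p else 0 for c in choices)
        for n in internals:
            if n.parent_node is not None:
                cost += 1 if assign[id(n)] != assign[id(n.parent_node)] else 0
        if cost < best:
            best = cost
            winners = {id(n): {assign[id(n)]} for n in internals}
        elif cost == best:
            for n in internals:
                winners[id(n)].add(assign[id(n)])
    return int(best), {k: frozenset(v) for k, v in winners.items()}


# ---------------------------------------------------------------------------
# Inference levels and the muscle map
# ---------------------------------------------------------------------------

@dataclass
class InferenceLevel:
    level: str  # "I", "I'", "II", "II'"
    rationale: str

    def bracket(self) -> str:
        return f"[{self.level}]"


def epb_level(node_state_set, crocodylian_state=None, outgroup_state=None,
              correlate_present: bool = True) -> InferenceLevel:
    """Witmer inference level from a reconstructed ancestral state set.

    An unambiguous (singleton) reconstruction agreeing with the extant
    bracket is level I; an ambiguous set is level II; the prime mark is
    added when the fossil lacks a clear osteological correlate. Unknown
    bracket states propagate to II'.
    """
    node_state_set = set(node_state_set) if node_state_set else set()
    unknown_bracket = crocodylian_state is None and outgroup_state is None \
        and not node_state_set
    if unknown_bracket:
        return InferenceLevel("II'", "bracket states unknown")
    singleton = len(node_state_set) == 1
    if singleton:
        level = "I"
        why = f"unambiguous ancestral state {next(iter(node_state_set))}"
    else:
        level = "II"
        why = f"ambiguous ancestral states {sorted(node_state_set)}"
    if not correlate_present:
        level += "'"
        why += "; no clear osteological correlate on the fossil"
    else:
        why += "; osteological correlate present"
    return InferenceLevel(level, why)


def load_attachment_dictionary(path=None) -> pd.DataFrame:
    """The packaged pelvic-limb attachment dictionary (37 muscles): acronym,
    full name, origin/insertion descriptions and inference levels."""
    if path is None:
        from importlib.resources import files

        path = files("paleolimb.data") / "gracilisuchus_muscles.csv"
        with path.open() as fh:
            return pd.read_csv(fh)
    return pd.read_csv(path)


def build_muscle_map(attachments: pd.DataFrame,
                     state_map: AncestralStateMap = None,
                     char_for_attachment: dict = None) -> pd.DataFrame:
    """Render the muscle map: one row per muscle with origin and insertion
    plus inference levels in bracket style.

    If a parsimony ``state_map`` and a mapping (acronym, "origin"/"insertion")
    -> character index are given, the level is recomputed from the root MPR
    set and the correlate flag; otherwise the dictionary's curated levels
    are rendered as-is.
    """
    required = {"acronym", "muscle", "origin", "insertion",
                "origin_level", "insertion_level"}
    missing = required - set(attachments.columns)
    if missing:
        raise ValueError(f"attachment dictionary missing columns: {sorted(missing)}")
    rows = []
    for _, r in attachments.iterrows():
        olev, ilev = r["origin_level"], r["insertion_level"]
        if state_map is not None and char_for_attachment:
            for key, col in ((r["acronym"], "origin"), (r["acronym"], "insertion")):
                ci = char_for_attachment.get((key, col))
                if ci is None:
                    raise ValueError(f"unmapped character for {key} {col}")
                correlate = bool(r.get(f"{col}_correlate", True))
                lev = epb_level(state_map.root_states(ci),
                                correlate_present=correlate).level
                if col == "origin":
                    olev = lev
                else:
                    ilev = lev
        rows.append({
            "muscle": r["muscle"],
            "acronym": r["acronym"],
            "origin": f"{r['origin']} [{olev}]",
            "insertion": f"{r['insertion']} [{ilev}]",
            "origin_level": olev,
            "insertion_level": ilev,
        })
    return pd.DataFrame(rows)
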