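"""Independent brute-force oracles used by several test modules."""

from rdkit import Chem

from kinfrags.enumeration import _assemble
from kinfrags.pairs import brics_link_compatible


def oracle_subset(library, per_pool=None):
    """A <= 20-fragment cross-pocket subset, small enough for the oracles."""
    per_pool = per_pool or {"AP": 8, "FP": 5, "SE": 4, "GA": 3}
    taken = {pool: 0 for pool in per_pool}
    keep = []
    for f in library.fragments():
        quota = per_pool.get(f.subpocket, 0)
        take = taken.get(f.subpocket, 0) < quota
        if take:
            taken[f.subpocket] += 1
        keep.append(take)
    return library.subset(keep)


def brute_force_pairs(library, adjacency):
    """Independent O(n^2) re-statement of the three pair-validity criteria."""
    fragments = library.fragments()
    found = []
    for i in range(len(fragments)):
        for j in range(i + 1, len(fragments)):
            a, b = fragments[i], fragments[j]
            if frozenset((a.subpocket, b.subpocket)) not in adjacency:
                continue
            hit = any(
                ap.neighbor_subpocket == b.subpocket
                and bp.neighbor_subpocket == a.subpocket
                and ap.bond_order == bp.bond_order
                and brics_link_compatible(ap.environment_type, bp.environment_type)
                for ap in a.attachments
                for bp in b.attachments
            )
            if hit:
                found.append((i, j))
    return found


def brute_force_molecules(library, adjacency, max_fragments=4, min_fragments=2, core="AP"):
    """Exhaustive enumeration oracle: try every fragment subset and junction
    assignment recursively; products assembled with the shared graph joiner
    (the search and deduplication logic is what this oracle cross-checks)."""
    fragments = list(enumerate(library.fragments()))
    results = set()

    def extend(nodes, bonds, used):
        if min_fragments <= len(nodes) <= max_fragments:
            try:
                product = _assemble(nodes, bonds)
                indices = tuple(sorted(i for i, _ in nodes))
                results.add((indices, Chem.MolToSmiles(product)))
            except Exception:
                pass
        if len(nodes) >= max_fragments:
            return
        used_pockets = {f.subpocket for _, f in nodes}
        for node_pos, (_, f) in enumerate(nodes):
            for att_pos, ap in enumerate(f.attachments):
                if (node_pos, att_pos) in used:
                    continue
                for new_idx, new_frag in fragments:
                    if new_frag.subpocket != ap.neighbor_subpocket:
                        continue
                    if new_frag.subpocket in used_pockets:
                        continue
                    if frozenset((f.subpocket, new_frag.subpocket)) not in adjacency:
                        continue
                    for new_att, new_ap in enumerate(new_frag.attachments):
                        if new_ap.neighbor_subpocket != f.subpocket:
                            continue
                        if new_ap.bond_order != ap.bond_order:
                            continue
                        if not brics_link_compatible(
                            ap.environment_type, new_ap.environment_type
                        ):
                            continue
                        extend(
                            nodes + [(new_idx, new_frag)],
                            bonds + [(node_pos, att_pos, len(nodes), new_att)],
                            used | {(node_pos, att_pos), (len(nodes), new_att)},
                        )

    for idx, f in fragments:
        if f.subpocket == core:
            extend([(idx, f)], [], set())
    return results
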