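"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: explicit loops over samples,
voxels and records, no shared code with the package's query/assembly
paths.
"""

import numpy as np

from atlasfuse.ingest import REGION_COL, VOXEL_COL


def brute_selection(ds, voi_mask, ont, parc, cell_types=None, meta=None):
    """Full-scan sample selection; returns (V, C, F) as lists of sample ids."""
    V, C, F = [], [], []
    region_cache = {}
    for sid in ds.samples:
        row = ds.sample_meta.loc[sid]
        if VOXEL_COL in ds.sample_meta.columns:
            i, j, k = np.unravel_index(int(row[VOXEL_COL]), voi_mask.shape)
            in_voi = bool(voi_mask[i, j, k])
        else:
            rid = int(row[REGION_COL])
            if rid not in region_cache:
                ids = set()
                stack = [rid]
                while stack:
                    r = stack.pop()
                    ids.add(r)
                    stack.extend(ont.children(r))
                region_cache[rid] = np.isin(parc.labels, list(ids))
            in_voi = bool((region_cache[rid] & voi_mask).any())
        if in_voi:
            V.append(sid)
        if cell_types is None or row["cell_type"] in cell_types:
            C.append(sid)
        ok = True
        if meta:
            for attr, allowed in meta.items():
                if row[attr] not in allowed:
                    ok = False
        if ok:
            F.append(sid)
    return V, C, F


def brute_mean(ds, sample_ids):
    out = {}
    for g in ds.genes:
        vals = [ds.values.at[g, s] for s in sample_ids]
        out[g] = sum(vals) / len(vals) if vals else np.nan
    return out


def brute_query(ds, V, C, F, kind):
    """Literal evaluation of the four query formulas per gene."""
    sel = [s for s in ds.samples if s in set(V) & set(C) & set(F)]
    if kind == "mean":
        denom_ids = None
    elif kind == "region-specificity":
        denom_ids = [s for s in ds.samples if s in set(C) & set(F)]
    elif kind == "celltype-specificity":
        denom_ids = [s for s in ds.samples if s in set(V) & set(F)]
    elif kind == "enrichment":
        denom_ids = list(V)
    else:
        raise ValueError(kind)
    num = brute_mean(ds, sel)
    if denom_ids is None:
        return num
    den = brute_mean(ds, denom_ids)
    return {g: (num[g] / den[g] if den[g] != 0 else np.nan) for g in ds.genes}


def brute_assemble(records, threshold, mirror=None):
    """Dict (source linear voxel) -> target weight array, max-combined."""
    shape = records[0].volume.shape
    effective = list(records)
    if mirror is not None:
        for rec in records:
            effective.append(rec.mirrored(mirror))
    rows = {}
    for rec in effective:
        img = rec.image.ravel()
        for v in rec.volume.linear:
            v = int(v)
            if v not in rows:
                rows[v] = img.copy()
            else:
                rows[v] = np.maximum(rows[v], img)
    for v in rows:
        w = rows[v].copy()
        w[w < threshold] = 0.0
        rows[v] = w
    return rows


def brute_resample(vol, source, target):
    """Exhaustive nearest-center search per target voxel (ties: lowest linear index)."""
    out = np.empty(target.shape, dtype=vol.dtype)
    src_coords = np.array(
        [[(i + 0.5) * source.voxel_size[0], (j + 0.5) * source.voxel_size[1], (k + 0.5) * source.voxel_size[2], i, j, k]
         for i in range(source.shape[0]) for j in range(source.shape[1]) for k in range(source.shape[2])]
    )
    for ti in range(target.shape[0]):
        for tj in range(target.shape[1]):
            for tk in range(target.shape[2]):
                c = np.array([(ti + 0.5) * target.voxel_size[0],
                              (tj + 0.5) * target.voxel_size[1],
                              (tk + 0.5) * target.voxel_size[2]])
                d = ((src_coords[:, :3] - c) ** 2).sum(axis=1)
                best = np.flatnonzero(d == d.min())[0]  # rows are in linear order
                i, j, k = src_coords[best, 3:].astype(int)
                out[ti, tj, tk] = vol[i, j, k]
    return out


def random_tree_doc(rng, n_nodes=50):
    """Random tree as a flat ontology document plus a parent map."""
    ids = list(range(1, n_nodes + 1))
    parents = {ids[0]: None}
    for i, nid in enumerate(ids[1:], start=1):
        parents[nid] = int(rng.choice(ids[:i]))
    doc = [{"id": i, "name": f"n{i}", "acronym": f"n{i}", "parent_structure_id": parents[i]}
           for i in ids]
    return doc, parents


def reachable_from(parents, root):
    """Brute-force reflexive-transitive closure per node via repeated scans."""
    children = {}
    for c, p in parents.items():
        children.setdefault(p, []).append(c)
    out = {}
    for start in parents:
        seen = set()
        frontier = [start]
        while frontier:
            n = frontier.pop()
            if n in seen:
                continue
            seen.add(n)
            frontier.extend(children.get(n, []))
        out[start] = seen
    return out
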