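"""Independent brute-force recomputation of every pipeline stage.

Nested loops over plain dict records, no interval index, no shared code with
the package — deliberately slow and obvious so it can serve as the oracle for
randomized equivalence tests.
"""

from __future__ import annotations

import math

ORIGIN_ORDER = {"not_de": 0, "de": 1}


def records(df):
    out = []
    for _, row in df.iterrows():
        r = dict(row)
        for k, v in r.items():
            if isinstance(v, float) and math.isnan(v):
                r[k] = None
        out.append(r)
    return out


def overlaps(a, b) -> bool:
    return (a["seqname"] == b["seqname"]
            and a["start"] <= b["end"] and b["start"] <= a["end"])


def brute_window(gene, flank):
    tss = gene["start"] if gene["strand"] != "-" else gene["end"]
    w = dict(gene)
    w["start"] = tss - flank
    w["end"] = tss + flank - 1
    return w


def brute_join(left, right, right_meta_cols):
    rows = []
    for l in left:
        hits = [r for r in right if overlaps(l, r)]
        if hits:
            for r in hits:
                row = dict(l)
                for c in right_meta_cols:
                    row[c] = r[c]
                rows.append(row)
        else:
            row = dict(l)
            for c in right_meta_cols:
                row[c] = None
            rows.append(row)
    return rows


def brute_merge(intervals):
    """Merge overlapping/book-ended closed intervals by repeated pairwise
    passes until nothing changes (different algorithm from the sort-scan in
    the implementation)."""
    ivs = [list(iv) for iv in intervals]
    changed = True
    while changed:
        changed = False
        out = []
        for iv in ivs:
            merged = False
            for o in out:
                if iv[0] <= o[1] + 1 and o[0] <= iv[1] + 1:
                    o[0] = min(o[0], iv[0])
                    o[1] = max(o[1], iv[1])
                    merged = True
                    changed = True
                    break
            if not merged:
                out.append(iv)
        ivs = out
    return sorted(tuple(iv) for iv in ivs)


def group_rows(rows, keys):
    groups = {}
    for row in rows:
        k = tuple(row[c] for c in keys)
        groups.setdefault(k, []).append(row)
    return groups


def _sort_key(keys, k):
    return tuple(ORIGIN_ORDER.get(v, v) if c == "origin" else v
                 for c, v in zip(keys, k))


def brute_gene_summary(joined):
    """Per (gene_id, origin): merged ranges, normalized peak count, max |LFC|."""
    out = []
    groups = group_rows(joined, ("gene_id", "origin"))
    for k in sorted(groups, key=lambda k: _sort_key(("gene_id", "origin"), k)):
        rows = groups[k]
        by_seq_strand = group_rows(rows, ("seqname", "strand"))
        n_res = len({r["resample"] for r in rows})
        n_peaks = sum(1 for r in rows if r["da_padj"] is not None)
        lfcs = [abs(r["da_log2FC"]) for r in rows if r["da_log2FC"] is not None]
        for (seq, strand), sub in sorted(by_seq_strand.items()):
            for s, e in brute_merge([(r["start"], r["end"]) for r in sub]):
                out.append({
                    "seqname": seq, "start": s, "end": e, "strand": strand,
                    "gene_id": k[0], "origin": k[1],
                    "peak_count": n_peaks / n_res,
                    "peak_max_lfc": max(lfcs) if lfcs else None,
                })
    return out


def brute_fixed(joined, thresholds=(1.0, 2.0)):
    """Per-origin peak counts (one stage) and gene counts (two stages)."""
    out = []
    by_origin = group_rows(joined, ("origin",))
    per_gene = group_rows(joined, ("gene_id", "origin", "resample"))
    for origin in sorted(by_origin, key=lambda k: ORIGIN_ORDER[k[0]]):
        rows = by_origin[origin]
        n_res = len({r["resample"] for r in rows})
        rec = {"origin": origin[0],
               "peak_count": sum(1 for r in rows
                                 if r["da_padj"] is not None) / n_res}
        for t in thresholds:
            peak = sum(1 for r in rows if r["da_log2FC"] is not None
                       and abs(r["da_log2FC"]) > t)
            gene = 0
            for k, g in per_gene.items():
                if k[1] != origin[0]:
                    continue
                c = sum(1 for r in g if r["da_log2FC"] is not None
                        and abs(r["da_log2FC"]) > t)
                if c > 0:
                    gene += 1
            rec[f"lfc{t:g}_gene_count"] = gene / n_res
            rec[f"lfc{t:g}_peak_count"] = peak / n_res
        out.append(rec)
    return out


def brute_sweep(joined, grid):
    """Per (origin, threshold): normalized gene and peak counts."""
    per_gene = group_rows(joined, ("gene_id", "origin", "resample"))
    counts = {}
    for k, g in per_gene.items():
        lfcs = [abs(r["da_log2FC"]) for r in g if r["da_log2FC"] is not None]
        counts[k] = [sum(1 for v in lfcs if v > t) for t in grid]
    origins = sorted({k[1] for k in counts}, key=ORIGIN_ORDER.get)
    out = []
    for origin in origins:
        ks = [k for k in counts if k[1] == origin]
        n_res = len({k[2] for k in ks})
        for i, t in enumerate(grid):
            gene = sum(1 for k in ks if counts[k][i] > 0)
            peak = sum(counts[k][i] for k in ks)
            out.append({"origin": origin, "threshold": t,
                        "gene_count": gene / n_res,
                        "peak_count": peak / n_res})
    return out
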