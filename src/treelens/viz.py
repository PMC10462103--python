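"""Static and self-contained HTML scatterplots of tree embeddings.

The HTML output approximates an interactive app without a server: the
scatter is inline SVG, and hovering a point reveals a thumbnail of that
tree rendered from its Newick, so outliers can be inspected in place.
"""

from __future__ import annotations

import html
import json
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .reduce import EmbeddingResult
from .tree import PhyloTree


def _axis_labels(emb: EmbeddingResult):
    if emb.method == "pca" and emb.var_explained is not None:
        return [f"PC{i + 1} ({100 * emb.var_explained[i]:.0f}% variance)"
                for i in range(emb.q)]
    return [f"MDS{i + 1}" for i in range(emb.q)]


def plot_embedding(emb: EmbeddingResult, out, highlight=(), phylo_names=(),
                   trees=None) -> Path:
    """Scatter of the first two embedding components.

    Phylogenomic trees are drawn as red diamonds; ``highlight`` names
    (e.g. flagged outliers) get text labels; categories color the
    points.  Writes PNG/SVG via matplotlib, or a self-contained HTML
    page (with hover tree thumbnails when ``trees`` is given) if ``out``
    ends in ``.html``.
    """
    if emb.q < 2:
        raise ValueError("plotting needs a q >= 2 embedding")
    out = Path(out)
    if out.suffix == ".html":
        return _plot_html(emb, out, highlight, phylo_names, trees)

    names = emb.tree_names or [f"tree_{i}" for i in range(emb.n_trees)]
    cats = emb.tree_categories or [""] * emb.n_trees
    xs, ys = emb.coords[:, 0], emb.coords[:, 1]
    fig, ax = plt.subplots(figsize=(7, 5.5))
    palette = plt.get_cmap("tab10")
    cat_levels = sorted({c for c, n in zip(cats, names) if n not in phylo_names})
    for ci, cat in enumerate(cat_levels):
        sel = [i for i in range(len(names))
               if cats[i] == cat and names[i] not in phylo_names]
        ax.scatter(xs[sel], ys[sel], s=28, alpha=0.8,
                   color=palette(ci % 10), label=cat or "gene tree")
    psel = [i for i in range(len(names)) if names[i] in phylo_names]
    if psel:
        ax.scatter(xs[psel], ys[psel], s=90, marker="D", color="red",
                   zorder=5, label="phylogenomic")
    for i, name in enumerate(names):
        if name in highlight:
            ax.annotate(name, (xs[i], ys[i]), textcoords="offset points",
                        xytext=(4, 4), fontsize=8)
    labels = _axis_labels(emb)
    ax.set_xlabel(labels[0])
    ax.set_ylabel(labels[1])
    ax.legend(fontsize=8, loc="best")
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out


# ---------------------------------------------------------------------------
# tiny SVG tree thumbnails + HTML scatter
# ---------------------------------------------------------------------------

def tree_svg(tree: PhyloTree, width: int = 280, height: int = 220) -> str:
    """Minimal rectangular phylogram of an unrooted tree.

    Drawn from the trifurcating base node used for Newick output; x is
    cumulative branch length, y spreads the leaves evenly.
    """
    from .tree import _direct_children  # shared nesting logic

    sides = sorted(tree.internal_edges, key=lambda s: (len(s.side), s.sort_key()))
    ycursor = [0.0]
    segs, tips = [], []

    def layout(item, x0):
        if isinstance(item, str):
            x1 = x0 + tree.external_edges[item]
            y = ycursor[0]
            ycursor[0] += 1.0
            segs.append((x0, x1, y, y))
            tips.append((x1, y, item))
            return y, x1
        x1 = x0 + tree.internal_edges[item]
        children = _direct_children(item.side, sides, tree)
        ys = [layout(c, x1)[0] for c in children]
        y = (min(ys) + max(ys)) / 2
        segs.append((x0, x1, y, y))
        segs.append((x1, x1, min(ys), max(ys)))
        return y, x1

    roots = _direct_children(frozenset(tree.leaf_labels), sides, tree, at_root=True)
    ys = [layout(c, 0.0)[0] for c in roots]
    segs.append((0.0, 0.0, min(ys), max(ys)))

    xmax = max(max(s[0], s[1]) for s in segs) or 1.0
    ymax = max(s[3] for s in segs) or 1.0
    pad, lab = 6, 48
    sx = (width - pad * 2 - lab) / xmax
    sy = (height - pad * 2) / ymax
    parts = [f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
             f'height="{height}" style="background:#fff">']
    for x0, x1, y0, y1 in segs:
        parts.append(f'<line x1="{pad + x0 * sx:.1f}" y1="{pad + y0 * sy:.1f}" '
                     f'x2="{pad + x1 * sx:.1f}" y2="{pad + y1 * sy:.1f}" '
                     'stroke="#333" stroke-width="1"/>')
    for x, y, label in tips:
        parts.append(f'<text x="{pad + x * sx + 2:.1f}" y="{pad + y * sy + 3:.1f}" '
                     f'font-size="8" font-family="sans-serif">'
                     f'{html.escape(label)}</text>')
    parts.append("</svg>")
    return "".join(parts)


_HTML_TEMPLATE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>tree embedding</title>
<style>
 body {{ font-family: sans-serif; }}
 .pt {{ cursor: pointer; }}
 #thumb {{ position: fixed; right: 16px; top: 16px; border: 1px solid #999;
          background: #fff; padding: 4px; min-width: 200px; }}
</style></head>
<body>
<h3>Tree embedding ({method})</h3>
<svg id="scatter" width="640" height="480" style="border:1px solid #ccc">{points}</svg>
<div id="thumb">hover a point</div>
<script>
var payloads = {payloads};
document.querySelectorAll('.pt').forEach(function (el) {{
  el.addEventListener('mouseenter', function () {{
    var p = payloads[el.dataset.name];
    document.getElementById('thumb').innerHTML =
      '<b>' + el.dataset.name + '</b><br>' + (p || '(no tree payload)');
  }});
}});
</script>
</body></html>
"""


def _plot_html(emb, out, highlight, phylo_names, trees) -> Path:
    xs, ys = emb.coords[:, 0], emb.coords[:, 1]
    names = emb.tree_names or [f"tree_{i}" for i in range(emb.n_trees)]
    w, h, pad = 640, 480, 30
    xr = (xs.min(), xs.max() if xs.max() > xs.min() else xs.min() + 1)
    yr = (ys.min(), ys.max() if ys.max() > ys.min() else ys.min() + 1)

    def px(x):
        return pad + (x - xr[0]) / (xr[1] - xr[0]) * (w - 2 * pad)

    def py(y):
        return h - pad - (y - yr[0]) / (yr[1] - yr[0]) * (h - 2 * pad)

    pts = []
    for i, name in enumerate(names):
        color = "red" if name in phylo_names else "#1f77b4"
        r = 7 if name in phylo_names else 5
        pts.append(f'<circle class="pt" data-name="{html.escape(name)}" '
                   f'cx="{px(xs[i]):.1f}" cy="{py(ys[i]):.1f}" r="{r}" '
                   f'fill="{color}" fill-opacity="0.75"/>')
        if name in highlight:
            pts.append(f'<text x="{px(xs[i]) + 6:.1f}" y="{py(ys[i]) - 6:.1f}" '
                       f'font-size="10">{html.escape(name)}</text>')
    payloads = {}
    if trees is not None:
        by_name = {t.name: t for t in trees}
        for name in names:
            if name in by_name:
                payloads[name] = tree_svg(by_name[name])
    page = _HTML_TEMPLATE.format(method=emb.method, points="".join(pts),
                                 payloads=json.dumps(payloads))
    out = Path(out)
    out.write_text(page)
    return out
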