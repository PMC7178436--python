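"""Figure assembly and export for the 3D genome-by-phenome landscape.

The plotted object is a renderer-independent :class:`FigureSpec`: one trace
per phenotype (the z-axis), each a sequence of points whose x is a chromosome
or segment label, y is -log10(p) (or the effect size in effect mode) and
whose colour is always -log10(p). Missing cells produce no point — gaps are
never interpolated, which is why the landscape is drawn as per-phenotype
ribbons rather than a continuous surface.

Export writes either a fully self-contained interactive HTML page (the
figure data is embedded as JSON and rendered client-side on a canvas with
hover dialogs; the file opens offline) or a static matplotlib image.
"""

from __future__ import annotations

import html as _html
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .annotation import GeneIntervalMap, map_snp_to_genes
from .ingest import MISSING, SummaryRecord
from .landscape import BinPeakGrid, Stratum

__all__ = ["FigurePoint", "FigureTrace", "FigureSpec", "landscape_figure",
           "heatmap_projection", "write_figure"]

#: Sentinel used for missing heatmap cells (distinct from 0, a real -log10 p).
HEATMAP_SENTINEL = math.nan


@dataclass(frozen=True)
class FigurePoint:
    x: int  # index into FigureSpec.x_labels
    y: float
    color: float  # always neglog10p
    hover: dict


@dataclass
class FigureTrace:
    phenotype: str
    points: list[FigurePoint] = field(default_factory=list)


@dataclass
class FigureSpec:
    """Renderer-independent description of one landscape figure."""

    view: str  # "genome" | "chromosome"
    y_mode: str  # "pvalue" | "effect"
    x_labels: list[str]
    phenotypes: list[str]
    traces: list[FigureTrace]
    stratum: Stratum | None = None
    title: str = ""
    warning: str | None = None

    def n_points(self) -> int:
        return sum(len(t.points) for t in self.traces)

    def all_snp_ids(self) -> list[str]:
        return [p.hover["snp_id"] for t in self.traces for p in t.points]


def _fmt(v: float | str) -> str:
    if isinstance(v, float):
        return MISSING if math.isnan(v) else f"{v:.6g}"
    return str(v)


def _hover_payload(rec: SummaryRecord, locus: str, genes: list[str]) -> dict:
    return {
        "phenotype": rec.phenotype,
        "chromosome": rec.chrom,
        "snp_id": rec.snp_id,
        "neglog10p": round(rec.neglog10p, 5),
        "effect": _fmt(rec.effect),
        "se": _fmt(rec.se),
        "allele1": rec.allele1,
        "allele2": rec.allele2,
        "locus": locus,
        "gene": ";".join(genes) if genes else MISSING,
    }


def landscape_figure(
    peaks: Mapping[tuple[int, str], SummaryRecord] | BinPeakGrid,
    mode: str = "pvalue",
    phenotype_order: list[str] | None = None,
    gene_map: GeneIntervalMap | None = None,
    gene_window_bp: int = 100_000,
    title: str = "",
) -> FigureSpec:
    """Assemble a figure from genome peaks or a single-chromosome grid.

    ``mode="pvalue"`` puts -log10(p) on y; ``mode="effect"`` puts the effect
    size (beta or OR) on y while the colour scale stays bound to -log10(p),
    so significance and effect magnitude are visible simultaneously.
    """
    if mode not in ("pvalue", "effect"):
        raise ValueError(f"mode must be 'pvalue' or 'effect', got {mode!r}")

    def annotate(rec: SummaryRecord) -> list[str]:
        if gene_map is None:
            return []
        return map_snp_to_genes(gene_map, rec.chrom, rec.pos, gene_window_bp)

    if isinstance(peaks, BinPeakGrid):
        grid = peaks
        x_labels = [grid.scheme.label(grid.chrom, s) for s in grid.retained]
        x_index = {s: i for i, s in enumerate(grid.retained)}
        phenos = phenotype_order or grid.phenotypes
        traces = []
        for pheno in phenos:
            trace = FigureTrace(phenotype=pheno)
            for seg in grid.retained:
                rec = grid.cells.get((seg, pheno))
                if rec is None:
                    continue
                y = rec.neglog10p if mode == "pvalue" else rec.effect
                trace.points.append(FigurePoint(
                    x=x_index[seg], y=y, color=rec.neglog10p,
                    hover=_hover_payload(rec, grid.scheme.label(grid.chrom, seg), annotate(rec)),
                ))
            traces.append(trace)
        spec = FigureSpec(view="chromosome", y_mode=mode, x_labels=x_labels,
                          phenotypes=list(phenos), traces=traces, stratum=grid.stratum,
                          title=title or f"chromosome {grid.chrom}")
    else:
        chroms = sorted({c for c, _ in peaks})
        x_labels = [str(c) for c in chroms]
        x_index = {c: i for i, c in enumerate(chroms)}
        phenos = phenotype_order or sorted({p for _, p in peaks})
        traces = []
        for pheno in phenos:
            trace = FigureTrace(phenotype=pheno)
            for chrom in chroms:
                rec = peaks.get((chrom, pheno))
                if rec is None:
                    continue
                y = rec.neglog10p if mode == "pvalue" else rec.effect
                trace.points.append(FigurePoint(
                    x=x_index[chrom], y=y, color=rec.neglog10p,
                    hover=_hover_payload(rec, f"chr{chrom}", annotate(rec)),
                ))
            traces.append(trace)
        spec = FigureSpec(view="genome", y_mode=mode, x_labels=x_labels,
                          phenotypes=list(phenos), traces=traces, title=title or "entire genome")
    if spec.n_points() == 0:
        spec.warning = "empty figure: no peaks to plot"
    return spec


def heatmap_projection(spec: FigureSpec) -> np.ndarray:
    """Project the figure onto the x/z plane: a (x, phenotype) -log10(p) matrix.

    The matrix is the flyover view of the landscape; cells with no point hold
    NaN (missing is distinct from a genuine 0).
    """
    mat = np.full((len(spec.x_labels), len(spec.phenotypes)), HEATMAP_SENTINEL)
    for j, trace in enumerate(spec.traces):
        for pt in trace.points:
            mat[pt.x, j] = pt.color
    return mat


def _spec_json(spec: FigureSpec) -> str:
    payload = {
        "view": spec.view,
        "y_mode": spec.y_mode,
        "title": spec.title,
        "x_labels": spec.x_labels,
        "phenotypes": spec.phenotypes,
        "stratum": None if spec.stratum is None else
            [spec.stratum.lo, None if math.isinf(spec.stratum.hi) else spec.stratum.hi],
        "traces": [
            {"phenotype": t.phenotype,
             "points": [{"x": p.x, "y": None if (isinstance(p.y, float) and math.isnan(p.y)) else p.y,
                         "c": p.color, "hover": p.hover}
                        for p in t.points]}
            for t in spec.traces
        ],
    }
    return json.dumps(payload, sort_keys=True, separators=(",", ":"))


_HTML_TEMPLATE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>__TITLE__</title>
<style>
 body{font-family:sans-serif;margin:1em}
 #wrap{position:relative}
 #hover{position:absolute;display:none;background:#fff;border:1px solid #888;
        padding:4px 8px;font-size:12px;pointer-events:none;white-space:pre}
 canvas{border:1px solid #ccc}
</style></head>
<body>
<h3>__TITLE__</h3>
<div id="wrap">
<canvas id="land" width="960" height="520"></canvas>
<canvas id="heat" width="960" height="260"></canvas>
<div id="hover"></div>
</div>
<script id="figdata" type="application/json">__DATA__</script>
<script>
const spec=JSON.parse(document.getElementById('figdata').textContent);
const colors=['#1f77b4','#ff7f0e','#2ca02c','#d62728','#9467bd','#8c564b',
              '#e377c2','#7f7f7f','#bcbd22','#17becf'];
let cmax=0; spec.traces.forEach(t=>t.points.forEach(p=>{if(p.c>cmax)cmax=p.c;}));
let ymax=0,ymin=0;
spec.traces.forEach(t=>t.points.forEach(p=>{if(p.y!==null){if(p.y>ymax)ymax=p.y;if(p.y<ymin)ymin=p.y;}}));
if(ymax===ymin)ymax=ymin+1;
const nx=Math.max(spec.x_labels.length,1), nz=Math.max(spec.phenotypes.length,1);
// oblique projection of (x, y, z) onto the landscape canvas
function proj(x,y,z){
  const px=60+(x/(nx))*760+(z/(nz))*120;
  const py=460-((y-ymin)/(ymax-ymin))*360-(z/(nz))*60;
  return [px,py];
}
const land=document.getElementById('land'),lc=land.getContext('2d');
const markers=[];
spec.traces.forEach((t,zi)=>{
  lc.strokeStyle=colors[zi%colors.length];lc.fillStyle=lc.strokeStyle;
  lc.beginPath();
  t.points.forEach((p,i)=>{
    if(p.y===null)return;
    const [px,py]=proj(p.x,p.y,zi);
    if(i===0)lc.moveTo(px,py);else lc.lineTo(px,py);
  });
  lc.stroke();
  t.points.forEach(p=>{
    if(p.y===null)return;
    const [px,py]=proj(p.x,p.y,zi);
    lc.beginPath();lc.arc(px,py,3,0,2*Math.PI);lc.fill();
    markers.push({px:px,py:py,hover:p.hover,canvas:'land'});
  });
  const [lx,ly]=proj(nx-0.5,ymax,zi);
  lc.fillText(t.phenotype,lx,ly);
});
// heatmap: x along columns, phenotype along rows; colour = -log10(p)
const heat=document.getElementById('heat'),hc=heat.getContext('2d');
const cw=900/nx, ch=220/nz;
function shade(c){const f=cmax>0?c/cmax:0;
  return 'rgb(255,'+Math.round(235*(1-f))+','+Math.round(59*(1-f))+')';}
spec.traces.forEach((t,zi)=>{
  t.points.forEach(p=>{
    hc.fillStyle=shade(p.c);
    hc.fillRect(40+p.x*cw,20+zi*ch,cw-1,ch-1);
    markers.push({px:40+p.x*cw+cw/2,py:20+zi*ch+ch/2,hover:p.hover,canvas:'heat'});
  });
  hc.fillStyle='#000';hc.fillText(t.phenotype,2,20+zi*ch+ch/2);
});
spec.x_labels.forEach((l,i)=>{hc.fillStyle='#000';hc.fillText(l,40+i*cw,250);});
const box=document.getElementById('hover');
function attach(canvas,name){
 canvas.addEventListener('mousemove',ev=>{
  const r=canvas.getBoundingClientRect();
  const mx=ev.clientX-r.left,my=ev.clientY-r.top;
  let best=null,bd=144;
  markers.forEach(m=>{if(m.canvas!==name)return;
    const d=(m.px-mx)*(m.px-mx)+(m.py-my)*(m.py-my);
    if(d<bd){bd=d;best=m;}});
  if(best){
    box.style.display='block';
    box.style.left=(ev.clientX-r.left+canvas.offsetLeft+12)+'px';
    box.style.top=(ev.clientY-r.top+canvas.offsetTop+12)+'px';
    box.textContent=Object.entries(best.hover).map(([k,v])=>k+': '+v).join('\\n');
  } else box.style.display='none';
 });
}
attach(land,'land');attach(heat,'heat');
</script>
</body></html>
"""


def write_figure(spec: FigureSpec, path: str | Path, format: str = "html") -> Path:
    """Write the figure as self-contained interactive HTML or a static image.

    HTML embeds the full figure data client-side, so the file opens offline
    with hover dialogs intact; with the same input the embedded data payload
    is byte-identical across runs. ``format="static"`` (or "png"/"svg")
    renders a matplotlib snapshot instead.
    """
    path = Path(path)
    if format == "html":
        doc = (_HTML_TEMPLATE
               .replace("__TITLE__", _html.escape(spec.title or "landscape"))
               .replace("__DATA__", _spec_json(spec)))
        path.write_text(doc)
        return path
    if format in ("static", "png", "svg"):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig = plt.figure(figsize=(10, 6))
        ax = fig.add_subplot(111, projection="3d")
        for zi, trace in enumerate(spec.traces):
            xs = [p.x for p in trace.points]
            ys = [zi] * len(trace.points)
            zs = [p.y for p in trace.points]
            if xs:
                ax.plot(xs, ys, zs, marker="o", markersize=3, label=trace.phenotype)
        ax.set_xticks(range(len(spec.x_labels)))
        ax.set_xticklabels(spec.x_labels, fontsize=6, rotation=60)
        ax.set_yticks(range(len(spec.phenotypes)))
        ax.set_yticklabels(spec.phenotypes, fontsize=7)
        ax.set_zlabel("-log10(p)" if spec.y_mode == "pvalue" else "effect size")
        ax.set_title(spec.title)
        if spec.traces:
            ax.legend(fontsize=6)
        fig.savefig(path)
        plt.close(fig)
        return path
    raise ValueError(f"unknown format {format!r}; use 'html' or 'static'")
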