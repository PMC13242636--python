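"""Self-contained HTML alignment report.

Packages one frame's alignment outcome into a single offline-viewable
dashboard: a summary (frame confidence, estimated canonical time and the
growth-band check), the coarse-sweep cost landscapes, the refinement
convergence traces, a candidate comparison table sorted by final cost,
and 3D scatter views colored by label and by confidence. All figures are
embedded as base64 PNG images; no network access is needed to view the
file.
"""

from __future__ import annotations

import base64
import html
import io as _io
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure

from .atlas import GrowthCurve
from .registration import FrameResult

OUT_OF_BAND_FLAG = "OUT OF GROWTH BAND"
Z_CRITICAL = 1.96  # 95% population band
_SD_FLOOR = 1e-9


def growth_curve_placement(n_cells: int, t_med: float,
                           curve: GrowthCurve) -> dict:
    """Locate a frame on the population growth curve.

    Returns ``z_score`` = (n_cells - bin mean) / bin sd for the bin
    containing t_med (sd floored at 1e-9) and ``in_band`` for |z| <= 1.96.
    A t_med outside the curve's span sets ``out_of_range`` instead of
    raising.
    """
    idx = curve.bin_index_for(t_med)
    if idx is None:
        return {"in_band": False, "z_score": float("nan"),
                "bin_index": None, "out_of_range": True}
    sd = max(float(curve.sds[idx]), _SD_FLOOR)
    z = (n_cells - float(curve.means[idx])) / sd
    return {"in_band": bool(abs(z) <= Z_CRITICAL), "z_score": float(z),
            "bin_index": idx, "out_of_range": False}


@dataclass
class ReportPayload:
    """Everything the dashboard renders for one aligned frame."""

    result: FrameResult
    growth_curve: GrowthCurve | None = None

    def missing_parts(self) -> list[str]:
        missing = []
        r = self.result
        if not r.landscapes:
            missing.append("coarse-sweep landscapes")
        if not r.candidates:
            missing.append("candidate summaries")
        if not r.candidate.trace:
            missing.append("refinement trace")
        if r.slice.t_med is None:
            missing.append("winning slice t_med")
        return missing


def _fig_to_b64(fig: Figure) -> str:
    buf = _io.BytesIO()
    FigureCanvasAgg(fig)
    fig.savefig(buf, format="png", dpi=90, metadata={"Software": "embalign"})
    return base64.b64encode(buf.getvalue()).decode("ascii")


def _img(fig: Figure, alt: str) -> str:
    return f'<img alt="{alt}" src="data:image/png;base64,{_fig_to_b64(fig)}"/>'


def _sweep_figure(result: FrameResult) -> Figure:
    fig = Figure(figsize=(6.5, 3.2))
    ax = fig.add_subplot(111)
    for i, ls in enumerate(result.landscapes):
        ax.plot(ls.angles, ls.costs, lw=1.2, label=f"seed {i} (+/-PC1)")
    ax.set_xlabel("sweep angle (deg)")
    ax.set_ylabel("Sinkhorn-weighted sq. distance")
    ax.set_title("coarse rotational sweep")
    ax.legend(fontsize=7)
    fig.tight_layout()
    return fig


def _trace_figure(result: FrameResult) -> Figure:
    fig = Figure(figsize=(6.5, 3.2))
    ax = fig.add_subplot(111)
    for c in result.candidates[:8]:
        style = "-" if c["refine_trace"] == list(result.candidate.trace) else "--"
        ax.semilogy(np.maximum(c["refine_trace"], 1e-16), style, lw=1.0,
                    label=f's{c["slice_index"]} a{c["seed_angle"]:.0f}')
    ax.set_xlabel("refinement iteration")
    ax.set_ylabel("soft-weighted cost")
    ax.set_title("refinement convergence traces")
    ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    return fig


def _scatter_figure(result: FrameResult) -> Figure:
    pts = result.frame.positions
    fig = Figure(figsize=(8.0, 3.6))
    ax1 = fig.add_subplot(121, projection="3d")
    n = len(pts)
    ax1.scatter(pts[:, 0], pts[:, 1], pts[:, 2], c=np.arange(n), cmap="tab20", s=28)
    for p, name in zip(pts, result.assigned_names):
        ax1.text(p[0], p[1], p[2], name, fontsize=5)
    ax1.set_title("assigned labels")
    ax2 = fig.add_subplot(122, projection="3d")
    conf = (result.confidences if result.confidences is not None
            else np.full(n, np.nan))
    colors = np.nan_to_num(np.asarray(conf, dtype=float), nan=0.5)
    sc = ax2.scatter(pts[:, 0], pts[:, 1], pts[:, 2], c=colors, cmap="RdYlGn",
                     vmin=0, vmax=1, s=28)
    fig.colorbar(sc, ax=ax2, shrink=0.7)
    ax2.set_title("per-cell confidence")
    fig.tight_layout()
    return fig


def _growth_figure(curve: GrowthCurve, t_med: float, n_cells: int) -> Figure:
    fig = Figure(figsize=(6.5, 3.0))
    ax = fig.add_subplot(111)
    x = curve.bin_starts + curve.bin_width / 2
    ax.plot(x, curve.means, color="k", lw=1.2, label="training mean")
    ax.fill_between(x, curve.means - Z_CRITICAL * curve.sds,
                    curve.means + Z_CRITICAL * curve.sds, alpha=0.25,
                    label="95% band")
    ax.plot([t_med], [n_cells], "r*", ms=12, label="this frame")
    ax.set_xlabel("canonical time")
    ax.set_ylabel("total cell count")
    ax.set_title("growth-curve placement")
    ax.legend(fontsize=7)
    fig.tight_layout()
    return fig


def render_report(payload: ReportPayload, path: str | Path,
                  timestamp: str | None = None) -> Path:
    """Write the dashboard for one aligned frame to a single HTML file.

    ``timestamp`` overrides the generation time recorded in the file;
    output is byte-stable for a fixed payload and timestamp.
    """
    missing = payload.missing_parts()
    if missing:
        raise ValueError(f"report payload incomplete; missing: {', '.join(missing)}")
    r = payload.result
    ts = timestamp or datetime.now(timezone.utc).isoformat(timespec="seconds")

    placement_html = ""
    growth_img = ""
    if payload.growth_curve is not None:
        placement = growth_curve_placement(r.frame.n_cells, r.t_med, payload.growth_curve)
        if placement["out_of_range"]:
            flag = f'<b class="warn">{OUT_OF_BAND_FLAG}</b> (t_med outside training span)'
        elif not placement["in_band"]:
            flag = f'<b class="warn">{OUT_OF_BAND_FLAG}</b> (z = {placement["z_score"]:.2f})'
        else:
            flag = f'within 95% band (z = {placement["z_score"]:.2f})'
        placement_html = f"<p>Growth placement: {flag}</p>"
        growth_img = _img(_growth_figure(payload.growth_curve, r.t_med, r.frame.n_cells),
                          "growth curve")

    conf_txt = ("n/a" if r.frame_confidence is None
                else f"{r.frame_confidence:.3f}")
    rows = "\n".join(
        f"<tr><td>{c['slice_index']}</td><td>{html.escape(str(c['seed_index']))}</td>"
        f"<td>{c['seed_angle']:.1f}</td><td>{c['final_cost']:.4f}</td>"
        f"<td>{len(c['refine_trace'])}</td><td>{c['converged']}</td></tr>"
        for c in r.candidates)

    doc = f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>EmbAlign report: {html.escape(r.frame.embryo_id)}/{r.frame.frame_index}</title>
<style>body{{font-family:sans-serif;margin:2em;max-width:60em}}
table{{border-collapse:collapse}}td,th{{border:1px solid #999;padding:2px 8px;font-size:12px}}
.warn{{color:#b00}}</style></head><body>
<!-- generated: {ts} -->
<h1>EmbAlign alignment report</h1>
<section id="summary">
<h2>Summary</h2>
<p>Frame: {html.escape(r.frame.embryo_id)} / {r.frame.frame_index} &mdash; {r.frame.n_cells} cells</p>
<p>Winning slice: N={r.slice.n}, t_med = {r.t_med:.2f} (canonical), total Mahalanobis cost = {r.total_cost:.4f}</p>
<p>Frame confidence: {conf_txt}</p>
{placement_html}
{growth_img}
</section>
<section id="sweep">
<h2>Coarse sweep landscape</h2>
{_img(_sweep_figure(r), "sweep landscape")}
</section>
<section id="refinement">
<h2>Refinement convergence</h2>
{_img(_trace_figure(r), "refinement traces")}
</section>
<section id="candidates">
<h2>Candidate comparison</h2>
<table><tr><th>slice</th><th>seed</th><th>angle</th><th>final cost</th><th>iters</th><th>converged</th></tr>
{rows}
</table>
</section>
<section id="spatial">
<h2>3D label and confidence views</h2>
{_img(_scatter_figure(r), "3d views")}
</section>
</body></html>
"""
    path = Path(path)
    path.write_text(doc)
    return path
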