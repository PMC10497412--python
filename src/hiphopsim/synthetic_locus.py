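"""Synthetic locus annotation generator.

Generates toy BED tracks with the statistical structure of real regulatory
locus inputs — protein-binding sites embedded mostly within open-chromatin
domains, plus sparse convergently oriented CTCF anchor pairs with variable
occupancy — so the whole pipeline can run without any external data.
Domain lengths are log-normal; sites are uniform within domains; CTCF
pair occupancies are Beta-distributed.  Everything is seeded.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotation_io import (BeadAnnotation, GenomicInterval,
                            build_bead_annotation, write_bed)
from .observables import ProbeRegion

__all__ = ["generate_toy_locus", "generate_three_probe_layout",
           "write_tracks"]


def generate_toy_locus(
    n_beads: int = 3000,
    seed: int = 0,
    bead_bp: int = 1000,
    n_open_domains: int = 20,
    open_domain_len_bp: tuple[float, float] = (20_000.0, 0.5),
    sites_per_domain: float = 3.0,
    orphan_site_rate: float = 0.1,
    n_ctcf_pairs: int = 8,
    ctcf_occupancy: tuple[float, float] = (4.0, 1.5),
    chrom: str = "chrS",
) -> tuple[dict[str, list[GenomicInterval]], BeadAnnotation]:
    """Generate annotation tracks for one synthetic locus.

    Parameters
    ----------
    open_domain_len_bp:
        (mean_bp, sigma_log) of the log-normal open-domain length
        distribution.
    sites_per_domain:
        Poisson mean of binding sites per open domain (at least one site
        per domain is kept so domains are never functionally empty).
    orphan_site_rate:
        Expected orphan (outside-domain) sites per in-domain site; 0 means
        every binding site lies inside an open domain.
    n_ctcf_pairs:
        Number of convergent CTCF anchor pairs (forward site left of its
        reverse partner), occupancies drawn Beta(*ctcf_occupancy*).

    Returns
    -------
    (tracks, annotation):
        ``tracks`` maps ``atac``/``h3k27ac``/``ctcf`` to interval lists;
        ``annotation`` is the discretized bead classification.
    """
    if min(n_beads, bead_bp, n_open_domains, n_ctcf_pairs) < 0:
        raise ValueError("parameters must be nonnegative")
    rng = np.random.default_rng(seed)
    L = n_beads * bead_bp
    region = GenomicInterval(chrom, 0, L)

    mean_len, sig = open_domain_len_bp
    mu = np.log(mean_len) - sig ** 2 / 2.0
    lengths = np.maximum(
        bead_bp, rng.lognormal(mu, sig, size=n_open_domains).astype(int))
    if lengths.sum() >= L:
        raise ValueError(
            f"requested open coverage {lengths.sum()} bp exceeds locus "
            f"length {L} bp")

    # non-overlapping placement: distribute the free length into gaps
    free = L - int(lengths.sum())
    gaps = rng.dirichlet(np.ones(n_open_domains + 1)) * free
    open_ivs: list[GenomicInterval] = []
    pos = 0
    for g, ln in zip(gaps, lengths):
        start = int(pos + g)
        open_ivs.append(GenomicInterval(chrom, start, start + int(ln)))
        pos = start + int(ln)

    site_w = bead_bp
    site_ivs: list[GenomicInterval] = []
    for iv in open_ivs:
        n_sites = max(1, rng.poisson(sites_per_domain))
        for _ in range(n_sites):
            s = int(rng.integers(iv.start, max(iv.start + 1, iv.end - site_w)))
            site_ivs.append(GenomicInterval(chrom, s, min(s + site_w, L)))
    if orphan_site_rate > 0:
        n_orphans = rng.poisson(orphan_site_rate * len(site_ivs))
        in_open = np.zeros(n_beads, dtype=bool)
        for iv in open_ivs:
            in_open[iv.start // bead_bp:
                    min(n_beads, (iv.end - 1) // bead_bp + 1)] = True
        closed_beads = np.nonzero(~in_open)[0]
        for b in rng.choice(closed_beads, size=min(n_orphans,
                                                   len(closed_beads)),
                            replace=False):
            s = int(b) * bead_bp
            site_ivs.append(GenomicInterval(chrom, s, s + site_w))

    a, b = ctcf_occupancy
    ctcf_ivs: list[GenomicInterval] = []
    taken: set[int] = set()
    for _ in range(n_ctcf_pairs):
        for _attempt in range(200):
            span = int(rng.integers(100, 400)) * bead_bp  # 100-400 kbp loops
            left = int(rng.integers(0, max(1, n_beads - span // bead_bp - 1)))
            right = left + span // bead_bp
            if left in taken or right in taken or right >= n_beads:
                continue
            occ = float(rng.beta(a, b))
            ctcf_ivs.append(GenomicInterval(
                chrom, left * bead_bp, (left + 1) * bead_bp, "+", occ))
            ctcf_ivs.append(GenomicInterval(
                chrom, right * bead_bp, (right + 1) * bead_bp, "-", occ))
            taken.update((left, right))
            break

    tracks = {"atac": site_ivs, "h3k27ac": open_ivs, "ctcf": ctcf_ivs}
    annotation = build_bead_annotation(region, tracks, bead_bp=bead_bp)
    return tracks, annotation


def write_tracks(tracks: dict[str, list[GenomicInterval]], outdir,
                 region: GenomicInterval, manifest: dict | None = None
                 ) -> dict[str, str]:
    """Write each track as BED6 plus a JSON manifest; returns file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, ivs in tracks.items():
        path = outdir / f"{name}.bed"
        write_bed(ivs, path, track_name=name, source_region=region)
        paths[name] = str(path)
    if manifest is not None:
        mpath = outdir / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        paths["manifest"] = str(mpath)
    return paths


def generate_three_probe_layout(annotation: BeadAnnotation,
                                span_bp: int = 200_000,
                                seed: int = 0) -> list[ProbeRegion]:
    """Gene probe flanked by upstream/downstream enhancer probes.

    Three disjoint probes of 35-40 kbp each are placed in the first locus
    copy: the outer probe edges span approximately ``span_bp``, with the
    gene probe centered between them.
    """
    rng = np.random.default_rng(seed)
    bp = annotation.bead_bp
    copy = annotation.copies[0]
    span_beads = span_bp // bp
    if span_beads > copy.n_beads:
        raise ValueError("probe span exceeds the locus copy")
    lens = [int(rng.integers(35_000, 40_001)) // bp for _ in range(3)]
    center = copy.start_bead + copy.n_beads // 2
    left_edge = center - span_beads // 2
    right_edge = center + span_beads // 2
    left_edge = max(copy.start_bead, left_edge)
    right_edge = min(copy.stop_bead, right_edge)
    urr = ProbeRegion("URR", left_edge, left_edge + lens[0], copy.copy_id)
    gene = ProbeRegion("gene", center - lens[1] // 2,
                       center - lens[1] // 2 + lens[1], copy.copy_id)
    drr = ProbeRegion("DRR", right_edge - lens[2], right_edge, copy.copy_id)
    probes = [urr, gene, drr]
    for p in probes:
        p.validate(annotation)
    if not (urr.stop_bead <= gene.start_bead
            and gene.stop_bead <= drr.start_bead):
        raise ValueError("probes overlap; increase span_bp")
    return probes
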