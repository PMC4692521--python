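"""Shared fixtures.

Expensive phantom computations (meshes, Laplace solves, the buried-sulcus
enhancement) are session-scoped so unit and acceptance tests reuse them.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest
from scipy import ndimage

from neoribbon import cortex_geometry as cg
from neoribbon import em_pv, phantoms, surface_metrics as sm
from neoribbon.io_core import PHANTOM_CGM_LEFT, PHANTOM_CSF, PHANTOM_WM

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def sphere30():
    """R=30 sphere: truth, reconstructed mesh, curvatures, summary."""
    truth = phantoms.make_sphere_phantom(30.0, 1.0, noise_sd=0.0, seed=0)
    mesh = sm.reconstruct_surface(truth.labels)
    curv = sm.vertex_curvatures(mesh)
    summary = sm.summarize_curvature(mesh, curv)
    return truth, mesh, curv, summary


@pytest.fixture(scope="session")
def shell_field_thickness():
    """4 mm spherical shell at 1 mm: solved Laplace field + thickness map."""
    truth = phantoms.make_shell_phantom(20.0, 24.0, 1.0)
    cgm, inner, outer = cg.ribbon_masks(truth.labels)
    field = cg.solve_laplace(cgm, inner, outer, truth.labels.spacing)
    tmap = cg.compute_thickness(field)
    return truth, field, tmap


@pytest.fixture(scope="session")
def slab_field_thickness():
    truth = phantoms.make_slab_phantom(4.0, 1.0)
    cgm, inner, outer = cg.ribbon_masks(truth.labels)
    field = cg.solve_laplace(cgm, inner, outer, truth.labels.spacing)
    tmap = cg.compute_thickness(field)
    return truth, field, tmap


@pytest.fixture(scope="session")
def buried_enhanced():
    """Default buried-sulcus ribbon phantom pushed through the sulci pipeline."""
    truth = phantoms.make_folded_ribbon_phantom(buried=True, noise_sd=0.0, seed=1)
    labels = truth.labels
    csf_post = ndimage.gaussian_filter((labels.data == PHANTOM_CSF).astype(float), 1.0)
    uncorrected = cg.cortical_thickness(labels)
    enhanced, shocks = cg.detect_and_enhance(labels, csf_post)
    corrected = cg.cortical_thickness(enhanced)
    return {
        "truth": truth,
        "labels": labels,
        "uncorrected": uncorrected,
        "enhanced": enhanced,
        "shocks": shocks,
        "corrected": corrected,
    }


@pytest.fixture(scope="session")
def pv_em_run():
    """PV-contaminated ribbon phantom segmented with and without the PV class."""
    truth = phantoms.make_folded_ribbon_phantom(
        buried=False, pv_boundary=True, noise_sd=8.0, seed=3
    )
    priors = truth.tissue_priors(2.0)
    plain = em_pv.fit_em_gmm(truth.intensity, priors)
    labels_plain = em_pv.hard_labels(
        plain.posteriors, truth.lut, plain.mask, truth.labels.affine
    )
    pv_priors, pv_id = em_pv.add_pv_class(priors, PHANTOM_CGM_LEFT, PHANTOM_WM, kappa=0.5)
    seed = em_pv.init_pv_params(
        plain.gaussian(PHANTOM_CGM_LEFT), plain.gaussian(PHANTOM_WM), pv_id
    )
    with_pv = em_pv.fit_em_gmm(
        truth.intensity, pv_priors, init={pv_id: (seed.mean, seed.variance)}
    )
    posteriors, labels_pv = em_pv.merge_pv_into_wm(
        with_pv, pv_id, PHANTOM_WM, truth.lut, truth.labels.affine
    )
    return {
        "truth": truth,
        "plain": plain,
        "with_pv": with_pv,
        "pv_id": pv_id,
        "labels_plain": labels_plain,
        "labels_pv": labels_pv,
        "posteriors": posteriors,
    }


@pytest.fixture(scope="session")
def atlas_cohort():
    return phantoms.make_atlas_cohort(n=50, seed=7, shape=(48, 48, 48))


def cgm_count(labels) -> int:
    return int((labels.data == PHANTOM_CGM_LEFT).sum())
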