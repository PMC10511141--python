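"""MNE, sLORETA, dipole scan, EMD and GMM clustering."""

import numpy as np
import pytest
from scipy.optimize import linprog

from tetfield import (NoisePriorParams, SourceEstimate, dipole_scan,
                      emd_to_dipole, gmm_cluster, mne, sloreta)


# ---------------------------------------------------------------------------
# MNE
# ---------------------------------------------------------------------------

def test_mne_identity_leadfield_matches_scalar_tikhonov():
    rng = np.random.default_rng(0)
    y = rng.normal(size=24)
    params = NoisePriorParams()
    lam = params.regularization(y, np.eye(24))
    est = mne(np.eye(24), y, params)
    assert np.allclose(est.values, y / (1 + lam ** 2), atol=1e-12)
    # identity lead field: mean row power 1, so lambda = nu/theta0 = 0.1
    assert lam == pytest.approx(0.1)
    # the bare-ratio convention switch reproduces theta0/nu = 10^(20/20)
    bare = NoisePriorParams(convention="ratio")
    assert bare.regularization(y, np.eye(24)) == pytest.approx(10.0)


def test_mne_zero_data_gives_zero_estimate():
    est = mne(np.eye(5), np.zeros(5))
    assert not est.values.any()


def test_mne_linear_in_data():
    rng = np.random.default_rng(1)
    L = rng.normal(size=(16, 40))
    y = rng.normal(size=16)
    params = NoisePriorParams()
    a = mne(L, y, params).values
    b = mne(L, 3.0 * y, params).values
    # lambda is scale-invariant (nu and theta0 both track max|y|), so the
    # estimate is exactly linear in y
    assert np.allclose(b, 3.0 * a, atol=1e-10)


# ---------------------------------------------------------------------------
# sLORETA
# ---------------------------------------------------------------------------

def test_sloreta_is_uniformly_scaled_mne_for_identity():
    rng = np.random.default_rng(2)
    y = rng.normal(size=12)
    params = NoisePriorParams()
    ratio = sloreta(np.eye(12), y, params).values / mne(np.eye(12), y,
                                                        params).values
    assert np.allclose(ratio, ratio[0])


def test_sloreta_zero_localization_error(leadfield_small):
    # noiseless data from the lead field's own columns: the standardized
    # map must peak exactly at the generating source
    lf, _ = leadfield_small
    rng = np.random.default_rng(3)
    for k in (2, 17, 33):
        moment = rng.normal(size=3)
        y = lf.source_block(k) @ moment
        est = sloreta(lf, y)
        power = est.per_source()
        assert int(np.argmax(power)) == k


def test_sloreta_depth_bias_flatter_than_mne(leadfield_small):
    # deep vs superficial single-dipole pairs: the ratio of map maxima
    # (deep / superficial) should sit closer to 1 for sLORETA than MNE
    lf, _ = leadfield_small
    r = np.linalg.norm(lf.sources.positions, axis=1)
    deep = int(np.argmin(r))
    shallow = int(np.argmax(r))
    mom = np.array([1.0, 1.0, 1.0]) / np.sqrt(3)
    ratios = {}
    for method in (mne, sloreta):
        peaks = {}
        for k in (deep, shallow):
            y = lf.source_block(k) @ mom
            peaks[k] = method(lf, y).per_source().max()
        ratios[method.__name__] = peaks[deep] / peaks[shallow]
    assert abs(np.log(ratios["sloreta"])) < abs(np.log(ratios["mne"]))


# ---------------------------------------------------------------------------
# dipole scan
# ---------------------------------------------------------------------------

def test_dipole_scan_reference_and_oracle():
    rng = np.random.default_rng(4)
    L = rng.normal(size=(20, 30))          # 10 positions x 3 dof via LeadField
    y_in = L[:, 3:6] @ np.array([1.0, -2.0, 0.5])
    from tetfield.fem import LeadField, SourceSpace
    from tetfield.surfaces import ElectrodeSet
    src = SourceSpace(positions=np.zeros((10, 3)),
                      orientations=np.zeros((10, 3, 3)),
                      host_tets=np.zeros(10, int),
                      compartments=np.zeros(10, int))
    lf = LeadField(matrix=L, electrodes=ElectrodeSet(np.zeros((20, 3))),
                   sources=src, electrode_nodes=np.zeros(20, int))
    est = dipole_scan(lf, y_in)
    assert est.values[1] == pytest.approx(1.0)
    # oracle: dense normal-equations least squares per position
    y = rng.normal(size=20)
    est2 = dipole_scan(lf, y)
    for l in range(10):
        Ll = L[:, 3 * l:3 * l + 3]
        coef = np.linalg.solve(Ll.T @ Ll, Ll.T @ y)
        r = y - Ll @ coef
        g = 1 - (r @ r) / (y @ y)
        assert est2.values[l] == pytest.approx(g, abs=1e-10)


def test_dipole_scan_invariances():
    rng = np.random.default_rng(5)
    L = rng.normal(size=(12, 9))
    from tetfield.fem import LeadField, SourceSpace
    from tetfield.surfaces import ElectrodeSet
    src = SourceSpace(positions=np.zeros((3, 3)),
                      orientations=np.zeros((3, 3, 3)),
                      host_tets=np.zeros(3, int), compartments=np.zeros(3, int))
    lf = LeadField(matrix=L, electrodes=ElectrodeSet(np.zeros((12, 3))),
                   sources=src, electrode_nodes=np.zeros(12, int))
    y = rng.normal(size=12)
    g1 = dipole_scan(lf, y).values
    g2 = dipole_scan(lf, 7.5 * y).values
    assert np.allclose(g1, g2, atol=1e-12)
    with pytest.raises(ValueError):
        dipole_scan(lf, np.zeros(12))


# ---------------------------------------------------------------------------
# EMD
# ---------------------------------------------------------------------------

def _ot_lp_oracle(weights, positions, target):
    """General optimal-transport linear program (scipy linprog)."""
    # decision variables: flow f_i from source i to the single target
    # (degenerate LP, but written as the generic assignment for the check)
    d = np.linalg.norm(positions - target[None, :], axis=1)
    res = linprog(c=d, A_eq=np.ones((1, len(d))), b_eq=[1.0],
                  bounds=[(0, w) for w in weights], method="highs")
    assert res.success
    return res.fun


def test_emd_reference_values_and_ot_agreement():
    pos = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [5, 5, 5]], float)
    est = SourceEstimate(np.array([1.0, 0, 0, 0]), "mne", 1)
    assert emd_to_dipole(est, [0, 0, 0], pos) == 0.0
    assert emd_to_dipole(est, [10, 0, 0], pos) == pytest.approx(10.0)

    rng = np.random.default_rng(6)
    pts = rng.uniform(-50, 50, size=(200, 3))
    vals = rng.random(200)
    est = SourceEstimate(vals, "mne", 1)
    target = np.array([3.0, -7.0, 12.0])
    closed = emd_to_dipole(est, target, pts)
    w = vals ** 2
    w = w / w.sum()
    lp = _ot_lp_oracle(w, pts, target)
    assert closed == pytest.approx(lp, abs=1e-8)


def test_emd_rejects_empty_estimate():
    est = SourceEstimate(np.zeros(4), "mne", 1)
    with pytest.raises(ValueError):
        emd_to_dipole(est, [0, 0, 0], np.zeros((4, 3)))


# ---------------------------------------------------------------------------
# GMM
# ---------------------------------------------------------------------------

def _blob_points(rng, centers, n_per=250, sd=2.0):
    pts = np.vstack([rng.normal(c, sd, size=(n_per, 3)) for c in centers])
    w = np.ones(len(pts))
    return pts, SourceEstimate(np.sqrt(w), "mne", 1)


def test_gmm_recovers_two_separated_blobs():
    rng = np.random.default_rng(7)
    centers = np.array([[0, 0, 0], [30.0, 0, 0]])
    pts, est = _blob_points(rng, centers)
    rep = gmm_cluster(est, pts, seed=1)
    assert rep.n_clusters == 2
    got = rep.means[np.argsort(rep.means[:, 0])]
    assert np.linalg.norm(got - centers, axis=1).max() < 2.0
    assert rep.weights.sum() == pytest.approx(1.0)
    assert (rep.ellipsoid_volumes > 0).all()


def test_gmm_single_blob_selects_one_cluster():
    rng = np.random.default_rng(8)
    pts, est = _blob_points(rng, np.array([[5.0, -3.0, 2.0]]))
    rep = gmm_cluster(est, pts, seed=1)
    assert rep.n_clusters == 1


def test_gmm_weight_normalization_and_determinism():
    rng = np.random.default_rng(9)
    pts, est = _blob_points(rng, np.array([[0, 0, 0], [25.0, 5.0, 0]]))
    a = gmm_cluster(est, pts, seed=4)
    b = gmm_cluster(est, pts, seed=4)
    assert np.array_equal(a.means, b.means)
    assert a.weights.sum() == pytest.approx(1.0)
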