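"""Session simulator: catalogs, scene order, reproducibility, calibration."""

import dataclasses
import io

import numpy as np
import pytest

from vreye.fixations import accumulate_fixations
from vreye.scenes import (
    ACTIVE,
    ACTIVE_SCENES,
    ALL_SCENES,
    BACKGROUND_CAT,
    MISCELLANEOUS,
    NEUTRAL,
    NEUTRAL_SCENES,
    ObjectCatalog,
    ObjectEntry,
    make_scene_catalog,
)
from vreye.session import write_session_log
from vreye.simulate import (
    SimConfig,
    SimConfigError,
    _rng,
    _simulate_scene,
    draw_scene_order,
    simulate_participant,
)


@pytest.mark.parametrize("scene", ALL_SCENES)
def test_catalog_composition(scene):
    catalog = make_scene_catalog(scene)
    n_active = len(catalog.by_category(ACTIVE))
    assert len(set(catalog.names())) == len(catalog)
    assert all(e.radius > 0 for e in catalog)
    assert len(catalog.by_category(MISCELLANEOUS)) >= 1
    assert len(catalog.by_category(BACKGROUND_CAT)) >= 1
    if scene in ACTIVE_SCENES:
        assert n_active >= 4
        assert len(catalog.by_category(NEUTRAL)) >= 4
    else:
        assert n_active == 0


def test_unknown_scene_rejected():
    with pytest.raises(ValueError, match="unknown scene"):
        make_scene_catalog("Casino")


def test_driving_reversal_recategorizes_street_video():
    default = make_scene_catalog("Driving")
    assert default.category_of("street_video") == BACKGROUND_CAT
    preset = make_scene_catalog("Driving", driving_street_video_neutral=True)
    assert preset.category_of("street_video") == NEUTRAL


def test_scene_order_alternates_and_is_seed_deterministic():
    for seed in range(20):
        order = draw_scene_order(seed)
        assert order == draw_scene_order(seed)
        assert [s in ACTIVE_SCENES for s in order] == [True, False] * 3
        assert sorted(order) == sorted(ALL_SCENES)


def test_scene_order_first_scene_uniform_over_seeds():
    """Over 600 seeds each Active scene opens ~1/3 of the time (+/- 5 pp)."""
    firsts = [draw_scene_order(seed)[0] for seed in range(600)]
    for scene in ACTIVE_SCENES:
        share = firsts.count(scene) / 600
        assert abs(share - 1 / 3) < 0.05


def test_simulation_reproducible_byte_for_byte(tmp_path, short_config):
    log1, _ = simulate_participant(short_config, 2)
    log2, _ = simulate_participant(short_config, 2)
    write_session_log(log1, tmp_path / "a")
    write_session_log(log2, tmp_path / "b")
    for f in sorted(p.name for p in (tmp_path / "a").iterdir()):
        assert (tmp_path / "a" / f).read_bytes() == (tmp_path / "b" / f).read_bytes()


def test_ground_truth_dwell_matches_events_and_sums_to_duration(short_config):
    """Oracle identity: dwell totals recomputed from the gaze_switch events
    equal the generator's realized totals, and sum to scene duration."""
    log, truth = simulate_participant(short_config, 0)
    catalogs = {s: make_scene_catalog(s) for s in ALL_SCENES}
    for name, session in log.sessions.items():
        ledger = accumulate_fixations(session.events, catalogs[name],
                                      session.duration_ms)
        recomputed = {}
        for mapping in ledger.by_category.values():
            recomputed.update(mapping)
        gt = {k: v for k, v in truth.scenes[name].dwell_totals_ms.items() if v > 0}
        assert recomputed == pytest.approx(gt)
        assert sum(gt.values()) == session.duration_ms


def test_gaze_switch_events_agree_with_object_column(short_config):
    log, _ = simulate_participant(short_config, 1)
    for session in log.sessions.values():
        objects = session.samples["object"].to_numpy(dtype=object)
        t = session.samples["t_ms"].to_numpy()
        switches = [ev for ev in session.events if ev.kind == "gaze_switch"]
        for ev in switches:
            assert objects[int(ev.t_ms) // 10] == ev.payload["object"]
        # object changes in the column occur exactly at switch times
        change_ticks = np.flatnonzero(objects[1:] != objects[:-1]) + 1
        assert sorted(int(t[i]) for i in change_ticks) == \
               sorted(ev.t_ms for ev in switches[1:])


def test_both_pupils_missing_during_true_blinks(short_config):
    log, truth = simulate_participant(short_config, 0)
    for name, session in log.sessions.items():
        pl = session.samples["pupil_l_mm"].to_numpy()
        pr = session.samples["pupil_r_mm"].to_numpy()
        for onset_ms, dur_ms in truth.scenes[name].blinks:
            lo, hi = onset_ms // 10, (onset_ms + dur_ms) // 10
            assert np.isnan(pl[lo:hi]).all() and np.isnan(pr[lo:hi]).all()


def test_symmetric_catalog_unbiased_dwell():
    """dwell_bias = 1 over a symmetric catalog: category totals agree within
    3 SE over 50 scenes."""
    entries = []
    for i in range(4):
        entries.append(ObjectEntry(f"a{i}", ACTIVE, (float(i), 1.0, 2.0), 0.1))
        entries.append(ObjectEntry(f"n{i}", NEUTRAL, (float(i), 1.0, 3.0), 0.1))
    catalog = ObjectCatalog(entries)
    cfg = SimConfig(seed=37, scene_duration_ms=30_000, dwell_bias=1.0)
    diffs = []
    for k in range(50):
        rng = _rng(cfg.seed, 800, k)
        _, events, truth = _simulate_scene(rng, cfg, "Patio", catalog, 1.0, 4.0)
        total_a = sum(v for n, v in truth.dwell_totals_ms.items() if n.startswith("a"))
        total_n = sum(v for n, v in truth.dwell_totals_ms.items() if n.startswith("n"))
        diffs.append(total_a - total_n)
    diffs = np.array(diffs)
    se = diffs.std(ddof=1) / np.sqrt(len(diffs))
    assert abs(diffs.mean()) < 3 * se


def test_blink_counts_poisson_calibrated():
    """Mean realized blink count over 200 five-minute scenes within 3 SE of
    rate x duration (Poisson oracle)."""
    cfg = SimConfig(seed=41, blink_rate_per_min=20.0)
    catalog = make_scene_catalog("Library")
    counts = []
    for k in range(200):
        rng = _rng(cfg.seed, 900, k)
        _, _, truth = _simulate_scene(rng, cfg, "Library", catalog, 1.0, 4.0)
        counts.append(len(truth.blinks))
    counts = np.array(counts)
    expected = 20.0 * 5
    se = np.sqrt(expected / len(counts))  # Poisson SE of the mean
    assert abs(counts.mean() - expected) < 3 * se


def test_null_cue_delta_equalizes_category_means(short_config):
    cfg = dataclasses.replace(short_config, pupil_cue_delta_mm=0.0,
                              pupil_cue_delta_sd_mm=0.0)
    _, truth = simulate_participant(cfg, 0)
    for scene_truth in truth.scenes.values():
        means = set(scene_truth.category_pupil_mean_mm.values())
        assert len(means) == 1


def test_fixation_direction_default_and_reversal_presets():
    """Active > Neutral cue time in Patio/BBQ under defaults; reversed in
    Driving under both the default bias and the street-video preset."""
    def totals(scene, config):
        catalog = make_scene_catalog(
            scene, driving_street_video_neutral=config.driving_reversal)
        ta = tn = 0.0
        for k in range(5):
            rng = _rng(config.seed, 950, k)
            _, _, truth = _simulate_scene(rng, config, scene, catalog, 1.0, 4.0)
            for entry in catalog:
                if entry.category == ACTIVE:
                    ta += truth.dwell_totals_ms[entry.name]
                elif entry.category == NEUTRAL:
                    tn += truth.dwell_totals_ms[entry.name]
        return ta, tn

    cfg = SimConfig(seed=43, scene_duration_ms=60_000)
    for scene in ("Patio", "OutdoorBBQ"):
        ta, tn = totals(scene, cfg)
        assert ta > tn
    ta, tn = totals("Driving", cfg)
    assert ta < tn
    reversal = dataclasses.replace(cfg, driving_reversal=True)
    ta, tn = totals("Driving", reversal)
    assert ta < tn


def test_use_episode_coupling_induces_positive_bias_correlation():
    """With use_episodes_slope > 0, attentional bias correlates positively
    with 90-day use episodes across n = 200 participants."""
    from vreye.stats import pearson_r

    cfg = SimConfig(seed=47, n_participants=200, scene_duration_ms=30_000,
                    use_episodes_slope=0.25)
    biases, episodes = [], []
    catalogs = {s: make_scene_catalog(s) for s in ACTIVE_SCENES}
    for i in range(cfg.n_participants):
        _, truth = simulate_participant(cfg, i)
        per_scene = []
        for scene in ACTIVE_SCENES:
            gt = truth.scenes[scene].dwell_totals_ms
            catalog = catalogs[scene]
            ta = sum(gt[e.name] for e in catalog.by_category(ACTIVE))
            tn = sum(gt[e.name] for e in catalog.by_category(NEUTRAL))
            per_scene.append(ta - tn)
        biases.append(np.mean(per_scene))
        episodes.append(truth.use_episodes)
    r, p = pearson_r(biases, episodes)
    assert r > 0
    assert p < 0.05


def test_config_validation_errors():
    with pytest.raises(SimConfigError):
        SimConfig(blink_dur_ms_range=(40, 500)).validate()
    with pytest.raises(SimConfigError):
        SimConfig(dropout_dur_ms_range=(10, 60)).validate()
    with pytest.raises(SimConfigError):
        SimConfig(microsleep_dur_ms_range=(400, 900)).validate()
    with pytest.raises(SimConfigError):
        SimConfig(blink_rate_per_min=-1).validate()
    with pytest.raises(SimConfigError, match="unknown config keys"):
        SimConfig.from_dict({"blink_rate": 5})


def test_config_file_roundtrip(tmp_path):
    cfg = SimConfig(seed=9, n_participants=5, dwell_bias={"Patio": 3.0})
    for name in ("cfg.yaml", "cfg.json"):
        cfg.to_file(tmp_path / name)
        back = SimConfig.from_file(tmp_path / name)
        assert back == cfg
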