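"""Contact state machine: qualification, arming window, end-to-end run."""

from dataclasses import dataclass

import numpy as np
import pytest

from patchcontact.contactflow import (
    ContactEvent,
    ProcessConfig,
    ProcessInputs,
    ResistanceTrace,
    detect_contact,
    qualify_pipette,
    run_process,
)
from patchcontact.errors import InvalidSpecError, StreamAlignmentError
from patchcontact.stacks import TimedFrame
from patchcontact.synthscene import make_contact_sequence, make_process_inputs


def _trace(delta_rs, bath=5.0, dt=0.5, t0=1.0):
    times = t0 + np.arange(len(delta_rs)) * dt
    return ResistanceTrace(times=times,
                           resistance=bath + np.asarray(delta_rs, float),
                           bath_resistance=bath)


def _frames(n, dt=0.5, t0=1.0):
    img = np.full((64, 64), 150, np.uint8)
    return [TimedFrame(time_s=t0 + i * dt, image=img) for i in range(n)]


@dataclass
class _StubEstimate:
    defocus: float


class _StubModel:
    """Scripted defocus outputs; records when it was evaluated."""

    def __init__(self, values):
        self.values = list(values)
        self.calls = 0

    def next(self):
        v = self.values[min(self.calls, len(self.values) - 1)]
        self.calls += 1
        return _StubEstimate(defocus=v)


def _stub_predict(model, roi):
    return model.next()


class TestQualifyPipette:
    def test_in_range_ok(self):
        cfg = ProcessConfig(resistance_range_ok=(3.0, 8.0))
        assert qualify_pipette(_trace([0.0], bath=5.0), cfg) == "ok"

    def test_blow_then_replace(self):
        cfg = ProcessConfig(resistance_range_ok=(3.0, 8.0))
        high = _trace([0.0], bath=12.0)
        assert qualify_pipette(high, cfg) == "blow"
        assert qualify_pipette(high, cfg, after_blow=True) == "replace"

    def test_boundary_value_is_ok(self):
        cfg = ProcessConfig(resistance_range_ok=(3.0, 8.0))
        assert qualify_pipette(_trace([0.0], bath=8.0), cfg) == "ok"


class TestDetectContact:
    def test_contact_inside_window(self):
        """dR reaches 0.15 MOhm while the defocus reads 0.15 -> contact."""
        trace = _trace([0.0, 0.0, 0.1, 0.2, 0.3])
        model = _StubModel([0.35, 0.15, 0.1])
        descent = [(1.0 + 0.5 * i, 5.0 - i) for i in range(5)]
        event = detect_contact(_frames(5), trace, descent, model,
                               ProcessConfig(), (32, 32), predict=_stub_predict)
        assert event.status == "contact"
        assert event.defocus_at_event == 0.15
        assert event.delta_r_mohm == pytest.approx(0.2)

    def test_never_armed_runs_to_stream_end(self):
        trace = _trace([0.0, 0.0, 0.0, 0.05, 0.05])
        model = _StubModel([0.0])
        descent = [(1.0 + 0.5 * i, 5.0 - i) for i in range(5)]
        event = detect_contact(_frames(5), trace, descent, model,
                               ProcessConfig(), (32, 32), predict=_stub_predict)
        assert event.status == "no_contact_window_exceeded"
        assert model.calls == 0  # the network is never evaluated unarmed

    def test_window_ceiling_without_trigger(self):
        trace = _trace([0.0, 0.1, 0.3, 0.6, 0.8])
        model = _StubModel([0.9])
        descent = [(1.0 + 0.5 * i, 5.0 - i) for i in range(5)]
        event = detect_contact(_frames(5), trace, descent, model,
                               ProcessConfig(), (32, 32), predict=_stub_predict)
        assert event.status == "no_contact_window_exceeded"
        assert model.calls == 2  # frames at dR = 0.1 and 0.3 only

    def test_stream_misalignment_rejected(self):
        trace = _trace([0.0, 0.1], dt=0.5, t0=50.0)  # far from frame times
        with pytest.raises(StreamAlignmentError):
            detect_contact(_frames(3), trace, [(1.0, 5.0), (2.0, 4.0)],
                           _StubModel([0.0]), ProcessConfig(), (32, 32),
                           predict=_stub_predict)

    def test_higher_focus_threshold_cannot_delay_contact(self):
        """Raising the threshold can only declare contact earlier or at the
        same frame."""
        trace = _trace([0.0, 0.1, 0.2, 0.2, 0.3, 0.3])
        descent = [(1.0 + 0.5 * i, 5.0 - i) for i in range(6)]
        times = {}
        for thr in (0.1, 0.2, 0.35):
            model = _StubModel([0.5, 0.3, 0.15, 0.05])
            event = detect_contact(
                _frames(6), trace, descent, model,
                ProcessConfig(focus_threshold=thr), (32, 32),
                predict=_stub_predict)
            times[thr] = event.time_s if event.status == "contact" else np.inf
        assert times[0.35] <= times[0.2] <= times[0.1]

    def test_deterministic_for_fixed_inputs(self):
        trace = _trace([0.0, 0.1, 0.2])
        descent = [(1.0, 5.0), (1.5, 4.5), (2.0, 4.0)]
        events = []
        for _ in range(2):
            model = _StubModel([0.3, 0.1])
            events.append(detect_contact(_frames(3), trace, descent, model,
                                         ProcessConfig(), (32, 32),
                                         predict=_stub_predict))
        assert events[0] == events[1]

    def test_synthetic_sequence_trace_never_arms_before_contact(self):
        """Arming requires a quantised rise of at least 0.1 MOhm, which the
        generator only produces once the tip passed the contact height."""
        for seed in (0, 3):
            seq = make_contact_sequence(seed, render=False)
            trace, descent = seq["trace"], seq["descent"]
            for t, z in descent:
                r, _ = trace.at(t)
                if r - trace.bath_resistance >= 0.1:
                    assert z <= seq["contact_z"] + 0.26  # within one 0.25 um step


class TestRunProcess:
    def test_full_synthetic_run_ends_in_contact(self, trained_cunet):
        inputs, truth = make_process_inputs(0, trained_cunet)
        log = run_process(inputs)
        assert log["status"] == "contact"
        stages = [s["stage"] for s in log["stages"]]
        assert stages == ["qualify_pipette", "neuron_fusion",
                          "pipette_positioning", "contact_detection"]
        event = log["stages"][-1]
        assert abs(event["pipette_z_um"] - truth["contact_z_um"]) < 2.0

    def test_halts_when_no_neuron_survives_fusion(self):
        inputs, _ = make_process_inputs(1, _StubModel([0.0]))
        inputs.neuron_detections = inputs.neuron_detections[:2]  # too thin
        log = run_process(inputs)
        assert log["status"] == "neuron_not_found"
        assert len(log["stages"]) == 2

    def test_halts_on_focus_not_found(self):
        from patchcontact.synthscene import SceneSpec, render_focus_stack

        inputs, _ = make_process_inputs(2, _StubModel([0.0]))
        inputs.pipette_stack = render_focus_stack(
            SceneSpec(seed=2), (-25.0, -5.0), 1.0)  # sweep stays below tip
        log = run_process(inputs)
        assert log["status"] == "pipette_positioning_failed"
        assert log["stages"][-1]["stage"] == "pipette_positioning"

    def test_halts_on_bad_pipette(self):
        inputs, _ = make_process_inputs(3, _StubModel([0.0]))
        inputs.trace = ResistanceTrace(times=inputs.trace.times,
                                       resistance=inputs.trace.resistance,
                                       bath_resistance=15.0)
        log = run_process(inputs)
        assert log["status"] == "pipette_blow"
        assert len(log["stages"]) == 1
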