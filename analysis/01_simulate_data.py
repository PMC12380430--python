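"""Generate the reference synthetic dataset used by the downstream analyses.

Emulated design: one recorded population of 80 antennal-lobe projection
neurons; four blocks of 25 trials (hex and oct, each at high and low
intensity; 4-s odor pulses; 50-ms analysis bins); magnitude-only adaptation
(plateau 0.4, tau 5 trials).  Also simulates: palp-opening responses of 36
animals per odor pair, and a 30-trial catch session (hex repeated, iaa
deviant at trial 26).

Outputs under results/data/: spike events (CSV), trial tensors (HDF5),
behavior tables (CSV), protocol configs (YAML).
"""

from pathlib import Path

import odoradapt as oa

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 2024


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    proto = oa.StimulusProtocol(
        n_trials_per_block=25, odor_window_s=(0.0, 4.0),
        block_sequence=["hex_H", "hex_L", "oct_H", "oct_L"],
    )
    proto.to_yaml(OUT / "protocol_block.yaml")
    model = oa.make_population_model(odors=("hex", "oct"), protocol=proto, seed=SEED)
    events = oa.simulate_session(model, proto, seed=SEED)
    oa.write_spike_events(events, OUT / "spike_events_block.csv")
    tensor = oa.bin_spikes(events, proto, unit_labels=model.unit_labels())
    oa.write_tensor(tensor, OUT / "tensor_block.h5")
    print(f"block session: {len(events)} spikes -> tensor {tensor.shape}")

    catch_proto = oa.default_catch_protocol(repeated="hex_H", catch="iaa_H")
    catch_proto.to_yaml(OUT / "protocol_catch.yaml")
    catch_model = oa.make_population_model(odors=("hex",), protocol=catch_proto,
                                           extra_stimuli=("iaa_H",), seed=SEED)
    catch_events = oa.simulate_catch_session(catch_model, catch_proto, seed=SEED)
    oa.write_spike_events(catch_events, OUT / "spike_events_catch.csv")
    catch_tensor = oa.bin_spikes(catch_events, catch_proto,
                                 unit_labels=catch_model.unit_labels())
    oa.write_tensor(catch_tensor, OUT / "tensor_catch.h5")
    print(f"catch session: {len(catch_events)} spikes -> tensor {catch_tensor.shape}")

    bproto = oa.StimulusProtocol(n_trials_per_block=10, odor_window_s=(0.0, 4.0),
                                 block_sequence=["hex_H", "hex_L"])
    bproto.to_yaml(OUT / "protocol_behavior.yaml")
    bmodel = oa.BehaviorModel(n_animals=36)
    btable = oa.simulate_behavior(bmodel, bproto, seed=SEED)
    oa.write_behavior_table(btable, OUT / "behavior_block.csv")
    print(f"behavior: {len(btable)} responses from {bmodel.n_animals} animals")

    cbproto = oa.StimulusProtocol(
        n_trials_per_block=15, odor_window_s=(0.0, 4.0), block_sequence=["bza_H"],
        catch_trial_index=9, catch_stimulus="iaa_H",
    )
    cbproto.to_yaml(OUT / "protocol_behavior_catch.yaml")
    cbmodel = oa.BehaviorModel(p0=0.2, p_inf_high=0.85, tau_trials=2,
                               n_animals=36, p0_catch=0.2)
    cbtable = oa.simulate_behavior(cbmodel, cbproto, seed=SEED)
    oa.write_behavior_table(cbtable, OUT / "behavior_catch.csv")
    print(f"catch behavior: {len(cbtable)} responses")


if __name__ == "__main__":
    main()
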