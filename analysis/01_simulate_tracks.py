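"""Generate an example two-state single-molecule tracking dataset.

Simulates one field of view of molecules switching between free diffusion
(0.2 um^2/s) and transient confinement on a filament network (trapped
diffusion 0.002 um^2/s, binding 0.3 /s, unbinding 1.5 /s, 51 ms frames) and
writes the observed tracks plus the ground-truth trapped intervals under
scratch/tracks/ (the dataset runs to megabytes; downstream scripts
regenerate what they need from the seed instead of reading it back).
"""

from pathlib import Path

from slbkit.simgen import TwoStateSimConfig, simulate_two_state_tracks
from slbkit.tracks_io import write_tracks

OUT = Path(__file__).resolve().parent.parent / "scratch" / "tracks"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = TwoStateSimConfig(seed=1, n_frames=1200)
    tracks, truth = simulate_two_state_tracks(cfg)
    write_tracks(tracks, OUT / "tracks.csv")
    write_tracks(tracks, OUT / "tracks.xml")
    with open(OUT / "ground_truth_events.csv", "w") as fh:
        fh.write("track_id,start_time_s,end_time_s,zone_id\n")
        for e in truth:
            fh.write(f"{e.track_id},{e.start_time!r},{e.end_time!r},"
                     f"{e.zone_id}\n")
    mean_dur = sum(e.duration for e in truth) / len(truth)
    print(f"{len(tracks)} tracks over {cfg.n_frames} frames "
          f"({cfg.n_frames * cfg.frame_interval:.1f} s)")
    print(f"{len(truth)} ground-truth confinement events, "
          f"mean duration {mean_dur:.3f} s "
          f"(expected 1/k_unbind = {1 / cfg.k_unbind:.3f} s)")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
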