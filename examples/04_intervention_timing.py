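"""When should truth-tellers enter the network?

Delays transmitter activation to different entry times and reports the
resulting rumor peak: the later the truth enters, the taller the
infected peak and the weaker the transmitter response.
"""

from snitr import delayed_transmitter_run
from snitr.presets import INTERVENTION_BASE, INTERVENTION_INIT

print(" entry time | peak infected | peak transmitter | N-density peaks")
for t_enter in (1, 4, 8, 12, 17, 25):
    r = delayed_transmitter_run(
        INTERVENTION_BASE, t_enter, seed_fraction=0.01,
        init=INTERVENTION_INIT, t_end=60.0,
    )
    print(f"   {t_enter:7.0f} |      {r.max_i:.4f} |          {r.max_t:.4f} |"
          f" {r.n_peaks:8d}")
print("Earlier truth-teller entry lowers the rumor's peak; once the "
      "unopposed epidemic has already peaked (~t=12), debunking no "
      "longer reduces it.")
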