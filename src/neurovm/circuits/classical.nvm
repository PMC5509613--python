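# Classical conditioning (aplysia withdrawal reflex).
# sense(us)/sense(cs) are sensory threads; motor(us)/motor(cs) drive the
# withdrawal effector.  sense(us) fires an ltp thread that joins on a
# modulatory token merged by sense(cs): the weight between sense(cs) and
# motor(cs) is incremented only when the two stimuli coincide within one
# trial.  Weights are written for threshold 1: open pathway = 1, closed = 0.

model classical

fiber net {
  thread sense(us): [fire(ltp(sense(cs), motor(cs))), fire(motor(us)), send(motor(us))]
  thread sense(cs): [merge(ltp(sense(cs), motor(cs))), fire(motor(cs)), send(motor(cs))]
  thread motor(us): [receive(sense(us)), emit(withdraw(us))]
  thread motor(cs): [receive(sense(cs)), emit(withdraw(cs))]
}

weights {
  net: sense(us) -> motor(us) = 1
  net: sense(cs) -> motor(cs) = 0
}

sensors {
  us -> net: sense(us)
  cs -> net: sense(cs)
}
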