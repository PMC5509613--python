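# Simple operant conditioning (pigeon probing food).
# A perceived item is a feature vector I ([mat, smooth] = grain,
# [shiny, smooth] = pebble).  Initially the pathway sense(I) ->
# learn(accept(I)) is open and the pathways to accept(I)/reject(I) are
# closed, so every presentation is probed.  The excite/inhibit feedback of
# the previous probe (reward or punishment, judged against the accept set)
# drives ltp of the appropriate action pathway and ltd of the learn
# pathway, until the item is accepted or rejected without probing.
# Weight declarations are ground per item: operant learning here is
# item-specific.

model operant_simple

fiber net {
  thread sense(I): [fire(learn(accept(I))), send(learn(accept(I))), fire(accept(I)), send(accept(I)), fire(reject(I)), send(reject(I))]
  thread learn(accept(I)): [{excite(accept(I)) -> [fire(ltp(sense(I), accept(I))), merge(ltp(sense(I), accept(I))), fire(ltd(sense(I), learn(accept(I)))), merge(ltd(sense(I), learn(accept(I))))] ; inhibit(accept(I)) -> [fire(ltp(sense(I), reject(I))), merge(ltp(sense(I), reject(I))), fire(ltd(sense(I), learn(accept(I)))), merge(ltd(sense(I), learn(accept(I))))] ; always -> [receive(sense(I)), emit(probe(I))]}]
  thread accept(I): [receive(sense(I)), emit(accept(I))]
  thread reject(I): [receive(sense(I)), emit(reject(I))]
}

weights {
  net: sense([mat, smooth]) -> learn(accept([mat, smooth])) = 1
  net: sense([mat, smooth]) -> accept([mat, smooth]) = 0
  net: sense([mat, smooth]) -> reject([mat, smooth]) = 0
  net: sense([shiny, smooth]) -> learn(accept([shiny, smooth])) = 1
  net: sense([shiny, smooth]) -> accept([shiny, smooth]) = 0
  net: sense([shiny, smooth]) -> reject([shiny, smooth]) = 0
}

accept {
  net: [mat, smooth]
}

sensors {
  item(I) -> net: sense(I)
}
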