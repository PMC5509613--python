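# Win/stay lose/shift (second level of animal awareness; hummingbirds).
# Each trial has two stages, delivered as two interrupts on this fiber.
# Information stage: a baited flower at corner C; the bird feeds and the
# visited corner is pushed into the short-term cache (which survives the
# stage boundary).  Choice stage: both corners hold a flower; the recall
# pathway, once opened by rewarded experience, pulls the cached corner and
# visits it (win/stay).  Before acquisition the ctl pathway visits a
# random corner commanded by the fetch stimulus; rewards potentiate
# sense(choice) -> recall and depress the random pathway.  There is no
# circuitry for exploiting inhibit feedback, which is exactly why a
# win/shift world defeats the trained bird.

model win_stay_lose_shift

fiber net {
  thread sense(info(C)): [fire(feed(C)), send(feed(C))]
  thread feed(C): [receive(sense(info(C))), push(last, corner(C)), emit(feed(C))]
  thread sense(choice): [fire(recall), send(recall)]
  thread recall: [receive(sense(choice)), pull(corner(X)), fire(stay(X)), send(stay(X))]
  thread stay(X): [receive(recall), emit(visit(X))]
  thread ctl: [{fetch(left) -> [fire(go(left)), send(go(left))] ; fetch(right) -> [fire(go(right)), send(go(right))]}]
  thread go(X): [receive(ctl), emit(visit(X))]
  thread learn(X): [{excite(visit(X)) -> [fire(ltp(sense(choice), recall)), merge(ltp(sense(choice), recall)), fire(ltd(ctl, go(X))), merge(ltd(ctl, go(X)))]}]
}

weights {
  net: sense(info(C)) -> feed(C) = 1
  net: sense(choice) -> recall = 0
  net: recall -> stay(X) = 1
  net: ctl -> go(left) = 1
  net: ctl -> go(right) = 1
}

sensors {
  info(C) -> net: sense(info(C))
  choice -> net: sense(choice)
}
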