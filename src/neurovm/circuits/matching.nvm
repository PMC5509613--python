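# Matching to sample (first level of animal awareness), three layers.
# Buttons a and b carry colors I and J (one green, one red); c is the
# sample with color K.  Outer layers: each button thread addresses a match
# detector tagged with its own color, while the sample fires the detectors
# tagged with the sample's color — so match(X, C) can only ever receive
# when button X's color equals the sample's (address unification is the
# comparison, an innate structural pathway).  Middle layer: the fetch(a)/
# fetch(b) internal stimulus commands a random peck through ctl.  A
# rewarded trial (excite feedback) potentiates the color-generic
# match -> peck pathway and depresses the random-pecking pathway for the
# chosen button: the animal learns to match, then to choose the match.
# match -> peck weights are declared over the color variable, so what is
# learned is the rule, not a color arrangement.

model matching_to_sample

fiber net {
  thread sense(a, I): [send(match(a, I))]
  thread sense(b, J): [send(match(b, J))]
  thread sense(c, K): [fire(match(a, K)), fire(match(b, K))]
  thread match(X, C): [receive(sense(X, C)), fire(peck(X)), send(peck(X))]
  thread peck(X): [receive(match(X, C)), emit(peck(X))]
  thread ctl: [{fetch(a) -> [fire(choose(a)), send(choose(a))] ; fetch(b) -> [fire(choose(b)), send(choose(b))]}]
  thread choose(X): [receive(ctl), emit(peck(X))]
  thread learn(X): [{excite(peck(X, C)) -> [fire(ltp(match(X, C), peck(X))), merge(ltp(match(X, C), peck(X))), fire(ltd(ctl, choose(X))), merge(ltd(ctl, choose(X)))]}]
}

weights {
  net: sense(a, I) -> match(a, I) = 1
  net: sense(b, J) -> match(b, J) = 1
  net: match(a, I) -> peck(a) = 0
  net: match(b, J) -> peck(b) = 0
  net: ctl -> choose(a) = 1
  net: ctl -> choose(b) = 1
}

sensors {
  a(I) -> net: sense(a, I)
  b(J) -> net: sense(b, J)
  c(K) -> net: sense(c, K)
}
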