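# Categorize then sort (third level of animal awareness; chimpanzees).
# Two independent circuits, possibly active at different times, linked by
# the associative long-term memory protocol.
#
# Phase 1 (fiber memorize): each familiarization trial presents an object
# with its taste experience (excite(eat(X)) for edible, inhibit for not);
# the classify thread lays down a long-term trace {food(X)} or {toy(X)}
# and broadcasts a path to it.
#
# Phase 2 (fiber sort): showing an object fires two ltr threads; the one
# whose category was memorized recalls and fires recall(C, X).  Bin
# pathways recall(C, _) -> put(bin, C) are declared per *category* (the
# object is a variable), so a placement learned for the cake opens the
# food bin for every remembered food: sorting transfers to familiar
# objects never trained on.  The try pathway probes a random bin
# (fetch feedback loop) until the category is learned, then closes.

model categorize_sort

fiber memorize {
  thread sense(obj(X)): [fire(classify(X)), send(classify(X))]
  thread classify(X): [{excite(eat(X)) -> [receive(sense(obj(X))), emit(food(X)), lts(food(X)), broadcast(ltm(food(X)))] ; inhibit(eat(X)) -> [receive(sense(obj(X))), emit(toy(X)), lts(toy(X)), broadcast(ltm(toy(X)))]}]
}

fiber sort {
  thread sense(show(X)): [fire(ltr(food(X), sense(show(X)), recall(food, X))), fire(ltr(toy(X), sense(show(X)), recall(toy, X)))]
  thread recall(C, X): [fire(put(a, C)), send(put(a, C)), fire(put(b, C)), send(put(b, C)), fire(try(C, X)), send(try(C, X))]
  thread put(B, C): [receive(recall(C, X)), emit(put_in(B, X))]
  thread try(C, X): [receive(recall(C, X)), {fetch(a) -> [emit(put_in(a, X))] ; fetch(b) -> [emit(put_in(b, X))]}]
  thread learn(C, X, B): [{excite(sorted(C, X, B)) -> [fire(ltp(recall(C, X), put(B, C))), merge(ltp(recall(C, X), put(B, C))), fire(ltd(recall(C, X), try(C, X))), merge(ltd(recall(C, X), try(C, X)))]}]
}

weights {
  memorize: sense(obj(X)) -> classify(X) = 1
  sort: recall(food, X) -> put(a, food) = 0
  sort: recall(food, X) -> put(b, food) = 0
  sort: recall(toy, X) -> put(a, toy) = 0
  sort: recall(toy, X) -> put(b, toy) = 0
  sort: recall(food, X) -> try(food, X) = 1
  sort: recall(toy, X) -> try(toy, X) = 1
}

accept {
  memorize: cake
  memorize: orange
}

sensors {
  obj(X) -> memorize: sense(obj(X))
  show(X) -> sort: sense(show(X))
}
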