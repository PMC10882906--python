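# Packaged 12-item spiritual-care-needs instrument: 5 dimensions with
# 5/3/2/1/1 items, a 4-level Likert agreement scale, and the 5-category
# Kano answer scale used for the paired forward/reverse questions.
name: NSTS / K-NSTAs
likert_levels:
  - strongly disagree
  - disagree
  - agree
  - strongly agree
kano_levels:
  - Like
  - Should be
  - It doesn't matter
  - Bearable
  - Dislike
dimensions:
  - id: share_self_perception
    label: Share self-perception
  - id: help_thinking
    label: Help thinking
  - id: create_good_atmosphere
    label: Create a good atmosphere
  - id: explore_spiritual_beliefs
    label: Explore spiritual beliefs
  - id: help_religious_practice
    label: Help religious practice
items:
  - id: Q1
    label: Listen to me talking about my spiritual strengths.
    dimension: share_self_perception
  - id: Q2
    label: Listen to me talking about my spiritual concerns.
    dimension: share_self_perception
  - id: Q3
    label: Help me to think about my dreams.
    dimension: share_self_perception
  - id: Q4
    label: Teach me about ways to draw or write about my spirituality.
    dimension: share_self_perception
  - id: Q5
    label: Listen to the stories of my life.
    dimension: share_self_perception
  - id: Q6
    label: Ask me about religious practices.
    dimension: help_thinking
  - id: Q7
    label: Offer to talk with me about meditation.
    dimension: help_thinking
  - id: Q8
    label: Ask me about what gives my life meaning.
    dimension: help_thinking
  - id: Q9
    label: "Bring me humorous things, e.g. share a joke."
    dimension: create_good_atmosphere
  - id: Q10
    label: Help me to enjoy quiet times or space.
    dimension: create_good_atmosphere
  - id: Q11
    label: Ask me about my spiritual beliefs.
    dimension: explore_spiritual_beliefs
  - id: Q12
    label: Help me, if I needed, with my religious practices.
    dimension: help_religious_practice
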